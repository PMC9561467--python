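"""Hansen-style threshold regression inside the two-way fixed-effects model.

The key regressor's coefficient is allowed to switch when a threshold
variable q crosses an unknown gamma:

    y_it = b1 x_it I(q_it <= g) + b2 x_it I(q_it > g) + controls + phi_i + omega_t + e_it

gamma is estimated by minimizing the sum of squared residuals over the
observed values of q (SSR is piecewise constant between observed values, so
an interpolated lattice adds nothing); candidate values are trimmed at each
tail and must leave each regime at least a minimum occupancy share.  A
second threshold, when requested, is found by a conditional search holding
the first fixed, followed by one refinement pass of the first.  The
threshold effect is tested with a residual bootstrap of the F statistic
F = (S_null - S_alt) / sigma2, and the threshold itself is interval-estimated
by inverting the likelihood-ratio profile LR(g) = (S(g) - S(ghat)) / sigma2
against the critical value c(a) = -2 ln(1 - sqrt(1 - a))  (7.35 at a = 0.05).

Implementation note: all candidate regressors x*I(q <= g) are projected off
the fixed effects and controls once, and every SSR afterwards is evaluated
from the Gram matrix of those projected columns, which makes the full grid
search inside each bootstrap replicate a few thousand floating point
operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdSpec",
    "ThresholdFitResult",
    "threshold_ssr_profile",
    "estimate_threshold",
    "bootstrap_threshold_pvalue",
    "lr_confidence_set",
    "lr_critical_value",
    "plot_lr",
]


class NoThresholdError(RuntimeError):
    """Every candidate was rejected (empty regimes): no threshold estimable."""


@dataclass(frozen=True)
class ThresholdSpec:
    threshold_var: str
    dependent: str = "THEIL"
    key_regressor: str = "FASG"
    controls: tuple[str, ...] = ()
    max_thresholds: int = 1
    trim: float = 0.05
    min_regime_frac: float = 0.05
    n_boot: int = 300
    seed: int = 0
    unit_col: str = "province_id"
    time_col: str = "year"

    def __post_init__(self) -> None:
        if not 0.0 < self.trim < 0.5:
            raise ValueError("trim must lie in (0, 0.5)")
        if self.max_thresholds not in (1, 2):
            raise ValueError("max_thresholds must be 1 or 2")
        if self.n_boot < 1:
            raise ValueError("need at least one bootstrap replication")
        if self.threshold_var in self.controls:
            raise ValueError(
                "threshold variable must be excluded from the controls"
            )


@dataclass
class ThresholdFitResult:
    spec: ThresholdSpec
    thresholds: list
    regime_coefficients: pd.Series
    regime_std_errors: pd.Series
    control_coefficients: pd.Series
    ssr: float
    ssr_linear: float
    sigma2: float
    nobs: int
    df_resid: int
    r2_overall: float
    grid: np.ndarray
    ssr_profiles: list          # one (grid, ssr array) per threshold, conditional
    f_stats: dict = field(default_factory=dict)       # {1: F1, 2: F2}
    bootstrap_pvalues: dict = field(default_factory=dict)

    def lr_profile(self, which: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """LR(g) = (S(g) - S(ghat)) / sigma2 for threshold ``which`` (1-based)."""
        grid, prof = self.ssr_profiles[which - 1]
        smin = np.nanmin(prof)
        return grid, (prof - smin) / self.sigma2


# ---------------------------------------------------------------------------
# projection machinery
# ---------------------------------------------------------------------------

class _Demeaner:
    """Iterated two-way (unit and time) demeaning of column arrays."""

    def __init__(self, units, times, tol: float = 1e-10, max_iter: int = 200):
        self.u = pd.factorize(units)[0]
        self.t = pd.factorize(times)[0]
        self.nu = self.u.max() + 1
        self.nt = self.t.max() + 1
        self.cu = np.bincount(self.u).astype(float)
        self.ct = np.bincount(self.t).astype(float)
        self.tol = tol
        self.max_iter = max_iter

    def __call__(self, x: np.ndarray) -> np.ndarray:
        v = np.asarray(x, dtype=float)
        squeeze = v.ndim == 1
        if squeeze:
            v = v[:, None]
        v = v.copy()
        for _ in range(self.max_iter):
            usum = np.zeros((self.nu, v.shape[1]))
            np.add.at(usum, self.u, v)
            v -= (usum / self.cu[:, None])[self.u]
            tsum = np.zeros((self.nt, v.shape[1]))
            np.add.at(tsum, self.t, v)
            v -= (tsum / self.ct[:, None])[self.t]
            usum = np.zeros((self.nu, v.shape[1]))
            np.add.at(usum, self.u, v)
            if np.abs(usum / self.cu[:, None]).max() < self.tol:
                break
        return v[:, 0] if squeeze else v


class _ThresholdEngine:
    """Precomputed grid, projected split columns and Gram matrix."""

    def __init__(self, spec: ThresholdSpec, panel: pd.DataFrame):
        self.spec = spec
        need = [spec.dependent, spec.key_regressor, spec.threshold_var,
                *spec.controls]
        missing = [c for c in need if c not in panel.columns]
        if missing:
            raise KeyError(f"variables missing from panel: {missing}")
        df = (panel.dropna(subset=need)
              .sort_values([spec.unit_col, spec.time_col])
              .reset_index(drop=True))
        self.df = df
        self.n = len(df)
        self.y = df[spec.dependent].to_numpy(float)
        self.x = df[spec.key_regressor].to_numpy(float)
        self.q = df[spec.threshold_var].to_numpy(float)
        self.n_units = df[spec.unit_col].nunique()
        self.n_times = df[spec.time_col].nunique()
        self.demean = _Demeaner(df[spec.unit_col].to_numpy(),
                                df[spec.time_col].to_numpy())

        W = df[list(spec.controls)].to_numpy(float) if spec.controls else \
            np.empty((self.n, 0))
        self.W = self.demean(W) if W.size else W
        self.Wp = np.linalg.pinv(self.W) if W.size else None

        lo, hi = np.quantile(self.q, [spec.trim, 1.0 - spec.trim])
        uniq = np.unique(self.q)
        grid = uniq[(uniq >= lo) & (uniq <= hi)]
        n_le = np.searchsorted(np.sort(self.q), grid, side="right")
        frac = n_le / self.n
        keep = (frac >= spec.min_regime_frac) & (frac <= 1 - spec.min_regime_frac)
        grid, n_le = grid[keep], n_le[keep]
        if grid.size == 0:
            raise NoThresholdError("empty candidate grid after trimming")
        if grid.size < 10:
            raise ValueError(
                f"only {grid.size} candidate thresholds after trimming; need >= 10"
            )
        self.grid = grid
        self.n_le = n_le

        # projected split columns P[:, j] = M(x * I(q <= g_j)); last col = M x
        split = self.x[:, None] * (self.q[:, None] <= grid[None, :])
        P = np.column_stack([split, self.x])
        P = self.project(P)
        self.P = P
        self.G = P.T @ P
        self.e_idx = grid.size  # index of the unsplit column

        self.y_p = self.project(self.y)
        self.c_y = P.T @ self.y_p
        self.yy = float(self.y_p @ self.y_p)

        # absorbed df: two-way FE on (possibly unbalanced) panel
        self.absorbed = self.n_units + self.n_times - 1

    def project(self, v: np.ndarray) -> np.ndarray:
        """Demean by unit+time, then partial out the (demeaned) controls."""
        vd = self.demean(v)
        if self.W.size:
            vd = vd - self.W @ (self.Wp @ vd)
        return vd

    # --- SSR evaluation from the Gram matrix --------------------------------

    def ssr_linear(self, c=None, yy=None) -> float | np.ndarray:
        c = self.c_y if c is None else c
        yy = self.yy if yy is None else yy
        e = self.e_idx
        return yy - np.asarray(c)[e] ** 2 / self.G[e, e]

    def ssr_single(self, c=None, yy=None) -> np.ndarray:
        """SSR(g) for every grid candidate; supports batched c (ncand+1, R)."""
        c = self.c_y if c is None else c
        yy = self.yy if yy is None else yy
        G, e, m = self.G, self.e_idx, self.grid.size
        diag = np.diag(G)[:m]
        a11 = diag
        a12 = G[:m, e] - diag
        a22 = G[e, e] - 2.0 * G[:m, e] + diag
        det = a11 * a22 - a12**2
        c = np.asarray(c, dtype=float)
        batched = c.ndim == 2
        u = c[:m] if not batched else c[:m, :]
        v = (c[e] - c[:m]) if not batched else (c[e][None, :] - c[:m, :])
        if batched:
            a11 = a11[:, None]; a12 = a12[:, None]; a22 = a22[:, None]
            det = det[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            expl = (a22 * u**2 - 2.0 * a12 * u * v + a11 * v**2) / det
        bad = np.broadcast_to(det <= 1e-10 * max(self.G[e, e], 1.0) ** 2,
                              expl.shape)
        expl = np.where(bad, np.nan, expl)
        return yy - expl

    def _pair_gram(self, ja: int, jb: int):
        """3x3 Gram and index helpers for thresholds grid[ja] < grid[jb]."""
        G, e = self.G, self.e_idx
        g3 = np.array([
            [G[ja, ja], G[ja, jb] - G[ja, ja], G[ja, e] - G[ja, jb]],
            [0.0, G[jb, jb] - 2 * G[ja, jb] + G[ja, ja],
             G[jb, e] - G[jb, jb] - G[ja, e] + G[ja, jb]],
            [0.0, 0.0, G[e, e] - 2 * G[jb, e] + G[jb, jb]],
        ])
        g3 = g3 + np.triu(g3, 1).T
        return g3

    def _pair_c(self, ja: int, jb: int, c: np.ndarray) -> np.ndarray:
        return np.stack([c[ja], c[jb] - c[ja], c[self.e_idx] - c[jb]], axis=0)

    def ssr_double_conditional(self, j_fixed: int, c=None, yy=None) -> np.ndarray:
        """SSR over grid for a second threshold, first fixed at grid[j_fixed]."""
        c = self.c_y if c is None else c
        yy = self.yy if yy is None else yy
        m = self.grid.size
        out = np.full(m, np.nan)
        n_min = self.spec.min_regime_frac * self.n
        for j in range(m):
            if j == j_fixed:
                continue
            ja, jb = min(j, j_fixed), max(j, j_fixed)
            # middle-regime occupancy
            if (self.n_le[jb] - self.n_le[ja]) < n_min:
                continue
            g3 = self._pair_gram(ja, jb)
            cv = self._pair_c(ja, jb, c)
            try:
                b = np.linalg.solve(g3, cv)
            except np.linalg.LinAlgError:
                continue
            out[j] = yy - float(b @ cv)
        return out

    def regime_columns(self, thresholds: Sequence[float]) -> np.ndarray:
        """Projected regime regressors for the final split regression."""
        edges = [-np.inf, *sorted(thresholds), np.inf]
        cols = [self.x * ((self.q > lo) & (self.q <= hi))
                for lo, hi in zip(edges[:-1], edges[1:])]
        return self.project(np.column_stack(cols))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def threshold_ssr_profile(
    spec: ThresholdSpec,
    panel: pd.DataFrame,
    conditional_on: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """SSR over the candidate grid, optionally holding earlier thresholds fixed."""
    eng = _ThresholdEngine(spec, panel)
    if not conditional_on:
        return eng.grid, eng.ssr_single()
    if len(conditional_on) != 1:
        raise ValueError("at most one fixed threshold is supported")
    j_fixed = int(np.argmin(np.abs(eng.grid - conditional_on[0])))
    return eng.grid, eng.ssr_double_conditional(j_fixed)


def estimate_threshold(spec: ThresholdSpec, panel: pd.DataFrame) -> ThresholdFitResult:
    """Estimate threshold location(s) and regime coefficients.

    The first threshold minimizes the single-split SSR profile; with
    ``max_thresholds=2`` a second conditional search follows, and the first
    threshold is then refined once holding the second fixed.  Argmin ties
    break toward the smaller candidate.
    """
    eng = _ThresholdEngine(spec, panel)
    prof1 = eng.ssr_single()
    if np.all(np.isnan(prof1)):
        raise NoThresholdError("all candidates rejected in the single search")
    j1 = int(np.nanargmin(prof1))
    thresholds = [float(eng.grid[j1])]
    profiles = [(eng.grid.copy(), prof1)]
    f_stats: dict = {}

    n_params = 2 + len(spec.controls)
    df_resid = eng.n - eng.absorbed - n_params
    s_lin = float(eng.ssr_linear())
    s1 = float(prof1[j1])
    sigma2_1 = s1 / df_resid
    f_stats[1] = (s_lin - s1) / sigma2_1

    if spec.max_thresholds == 2:
        prof2 = eng.ssr_double_conditional(j1)
        if not np.all(np.isnan(prof2)):
            j2 = int(np.nanargmin(prof2))
            # one refinement pass of the first threshold given the second
            prof1r = eng.ssr_double_conditional(j2)
            j1r = int(np.nanargmin(prof1r)) if not np.all(np.isnan(prof1r)) else j1
            ja, jb = sorted((j1r, j2))
            thresholds = [float(eng.grid[ja]), float(eng.grid[jb])]
            profiles = [(eng.grid.copy(), prof1r), (eng.grid.copy(), prof2)]
            n_params = 3 + len(spec.controls)
            df_resid = eng.n - eng.absorbed - n_params
            s2 = float(np.nanmin(prof2))
            f_stats[2] = (s1 - s2) / (s2 / df_resid)

    # final split regression: regime columns + controls, classical SEs
    Z = eng.regime_columns(thresholds)
    k_regimes = Z.shape[1]
    X = np.column_stack([Z, eng.W]) if eng.W.size else Z
    yd = eng.demean(eng.y)
    beta, _, _, _ = np.linalg.lstsq(X, yd, rcond=None)
    resid = yd - X @ beta
    ssr = float(resid @ resid)
    n_params = X.shape[1]
    df_resid = eng.n - eng.absorbed - n_params
    if df_resid <= 0:
        raise NoThresholdError("not enough observations for the split model")
    sigma2 = ssr / df_resid
    V = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(V))

    key = spec.key_regressor
    if k_regimes == 2:
        names = [f"{key}|q<=g1", f"{key}|q>g1"]
    else:
        names = [f"{key}|q<=g1", f"{key}|g1<q<=g2", f"{key}|q>g2"]
    ctrl_names = list(spec.controls)
    r2 = _sq_corr(X @ beta, yd)
    return ThresholdFitResult(
        spec=spec,
        thresholds=thresholds,
        regime_coefficients=pd.Series(beta[:k_regimes], index=names),
        regime_std_errors=pd.Series(se[:k_regimes], index=names),
        control_coefficients=pd.Series(beta[k_regimes:], index=ctrl_names),
        ssr=ssr,
        ssr_linear=s_lin,
        sigma2=sigma2,
        nobs=eng.n,
        df_resid=df_resid,
        r2_overall=r2,
        grid=eng.grid.copy(),
        ssr_profiles=profiles,
        f_stats=f_stats,
    )


def _sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def bootstrap_threshold_pvalue(
    spec: ThresholdSpec,
    panel: pd.DataFrame,
    fit: Optional[ThresholdFitResult] = None,
    which: int = 1,
) -> tuple[float, float]:
    """Residual-bootstrap p-value of the threshold-effect F statistic.

    ``which=1`` tests one threshold against the linear model; ``which=2``
    tests a second threshold against the single-threshold model (the first
    threshold held at its sample estimate inside each replicate, the
    conventional sequential shortcut).  Regressors and estimated fixed
    effects are held fixed; the dependent variable is regenerated under the
    null from resampled residuals.  Identical seeds give identical p-values.
    """
    eng = _ThresholdEngine(spec, panel)
    rng = np.random.default_rng(spec.seed)
    R = spec.n_boot
    e_col = eng.e_idx

    prof1 = eng.ssr_single()
    j1 = int(np.nanargmin(prof1))
    s1 = float(prof1[j1])
    k_alt = 2 + len(spec.controls)

    if which == 1:
        # null: linear model
        s_null = float(eng.ssr_linear())
        df_alt = eng.n - eng.absorbed - k_alt
        sigma2 = s1 / df_alt
        f_obs = (s_null - s1) / sigma2
        b_null = eng.c_y[e_col] / eng.G[e_col, e_col]
        resid_null = eng.y_p - eng.P[:, e_col] * b_null
        # recentre to the full-model fitted values in the original space
        yhat = eng.y - resid_null

        draws = rng.integers(0, eng.n, size=(eng.n, R))
        Ystar = yhat[:, None] + resid_null[draws]
        Yp = eng.project(Ystar)
        c_all = eng.P.T @ Yp
        yy_all = np.einsum("ij,ij->j", Yp, Yp)
        s_null_star = eng.ssr_linear(c_all, yy_all)
        s_alt_star = np.nanmin(eng.ssr_single(c_all, yy_all), axis=0)
        f_star = (s_null_star - s_alt_star) / (s_alt_star / df_alt)
        p = float(np.mean(f_star >= f_obs))
        return float(f_obs), p

    if which == 2:
        prof2 = eng.ssr_double_conditional(j1)
        if np.all(np.isnan(prof2)):
            raise NoThresholdError("no admissible second threshold")
        s2 = float(np.nanmin(prof2))
        k2 = 3 + len(spec.controls)
        df2 = eng.n - eng.absorbed - k2
        sigma2 = s2 / df2
        f_obs = (s1 - s2) / sigma2
        # null: single-threshold model at the sample estimate
        Z = eng.regime_columns([float(eng.grid[j1])])
        X = np.column_stack([Z, eng.W]) if eng.W.size else Z
        yd = eng.demean(eng.y)
        beta, _, _, _ = np.linalg.lstsq(X, yd, rcond=None)
        resid_null = yd - X @ beta
        yhat = eng.y - resid_null

        draws = rng.integers(0, eng.n, size=(eng.n, R))
        Ystar = yhat[:, None] + resid_null[draws]
        Yp = eng.project(Ystar)
        c_all = eng.P.T @ Yp
        yy_all = np.einsum("ij,ij->j", Yp, Yp)
        s1_star_prof = eng.ssr_single(c_all, yy_all)
        j1_star = np.nanargmin(s1_star_prof, axis=0)
        s1_star = s1_star_prof[j1_star, np.arange(R)]
        f_star = np.empty(R)
        for r in range(R):
            p2 = eng.ssr_double_conditional(int(j1_star[r]), c_all[:, r],
                                            float(yy_all[r]))
            s2_star = np.nanmin(p2) if not np.all(np.isnan(p2)) else s1_star[r]
            f_star[r] = (s1_star[r] - s2_star) / (s2_star / df2)
        p = float(np.mean(f_star >= f_obs))
        return float(f_obs), p

    raise ValueError("which must be 1 or 2")


def lr_critical_value(alpha: float) -> float:
    """Hansen's asymptotic LR critical value c(a) = -2 ln(1 - sqrt(1 - a))."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-2.0 * np.log(1.0 - np.sqrt(1.0 - alpha)))


def lr_confidence_set(fit: ThresholdFitResult, alpha: float = 0.05) -> list[np.ndarray]:
    """Grid values whose LR profile lies below c(alpha), per threshold.

    Each returned set contains the corresponding point estimate (LR = 0
    there by construction).
    """
    c = lr_critical_value(alpha)
    sets = []
    for which in range(1, len(fit.thresholds) + 1):
        grid, lr = fit.lr_profile(which)
        sets.append(grid[np.where(np.nan_to_num(lr, nan=np.inf) <= c)])
    return sets


def plot_lr(fit: ThresholdFitResult, alpha: float = 0.05, path: str = "lr_plot.png"):
    """LR(g) profile per threshold with the c(alpha) reference line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = len(fit.thresholds)
    if n_panels == 0:
        raise ValueError("fit has no thresholds to plot")
    c = lr_critical_value(alpha)
    fig, axes = plt.subplots(1, n_panels, figsize=(5.5 * n_panels, 4.0),
                             squeeze=False)
    for k, ax in enumerate(axes[0]):
        grid, lr = fit.lr_profile(k + 1)
        ok = ~np.isnan(lr)
        ax.plot(grid[ok], lr[ok], lw=1.2, color="tab:blue")
        ax.axhline(c, color="tab:red", ls="--", lw=1.0,
                   label=f"{100 * (1 - alpha):.0f}% critical value {c:.2f}")
        ghat = fit.thresholds[k]
        ax.axvline(ghat, color="grey", ls=":", lw=0.8)
        ax.plot([ghat], [0.0], "o", ms=5, color="tab:blue")
        ax.set_xlabel(f"{fit.spec.threshold_var} threshold candidate")
        ax.set_ylabel("LR statistic")
        ax.set_title(f"threshold {k + 1}: {ghat:.4f}")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
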