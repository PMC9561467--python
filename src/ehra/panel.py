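"""Panel estimators for the province-year regression layer.

Two-way fixed effects are estimated by within-transformation (iterated
unit/time demeaning, which agrees with dummy-variable OLS); random effects
use Swamy-Arora-style variance components; instrumental-variables 2SLS
instruments the key regressor with its one-year lag inside the within
transformation.  Covariance options: classical, cluster-by-unit, and a
Driscoll-Kraay kernel estimator robust to heteroscedasticity, autocorrelation
and cross-sectional correlation jointly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "PanelFitResult",
    "within_transform",
    "fit_panel",
    "driscoll_kraay_cov",
    "cluster_cov",
    "hausman_test",
    "poolability_ftest",
    "vif",
    "fit_2sls",
]

logger = logging.getLogger(__name__)

Effects = Literal["none", "unit", "time", "unit+time"]
CovType = Literal["classical", "robust_3way", "cluster"]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message lists collinear columns."""


@dataclass(frozen=True)
class ModelSpec:
    """Variable roles for one panel model."""

    dependent: str
    key_regressor: str
    controls: tuple[str, ...] = ()
    effects: Effects = "unit+time"
    cov: CovType = "classical"
    unit_col: str = "province_id"
    time_col: str = "year"

    def __post_init__(self) -> None:
        regs = (self.key_regressor, *self.controls)
        if self.dependent in regs:
            raise ValueError("dependent variable cannot appear among regressors")
        if len(set(regs)) != len(regs):
            raise ValueError("duplicate regressor names")

    @property
    def regressors(self) -> tuple[str, ...]:
        return (self.key_regressor, *self.controls)


@dataclass
class PanelFitResult:
    params: pd.Series
    cov: pd.DataFrame
    std_errors: pd.Series
    nobs: int
    df_resid: int
    resid: np.ndarray
    fitted: np.ndarray
    r2_within: float
    r2_overall: float
    ssr: float
    estimator: str
    effects: str
    cov_type: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def tstats(self) -> pd.Series:
        return self.params / self.std_errors

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tstats), df=max(self.df_resid, 1)),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, df=max(self.df_resid, 1))
        return pd.DataFrame(
            {"lower": self.params - q * self.std_errors,
             "upper": self.params + q * self.std_errors}
        )


# ---------------------------------------------------------------------------
# within transformation
# ---------------------------------------------------------------------------

def within_transform(
    panel: pd.DataFrame,
    columns: Sequence[str],
    effects: Effects = "unit+time",
    unit_col: str = "province_id",
    time_col: str = "year",
    tol: float = 1e-10,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Demean ``columns`` within units and/or periods.

    For ``unit+time`` the demeaning is iterated until every unit mean and
    period mean of every column is below ``tol`` (one pass suffices on a
    balanced panel; unbalanced panels need a few sweeps, equivalent to
    projecting on the unit+time dummy space).  Units or periods with a single
    observation are dropped with a warning (their within value is identically
    zero and they contribute no information).
    """
    df = panel.sort_values([unit_col, time_col]).reset_index(drop=True).copy()
    if effects == "none":
        return df
    for key in ([unit_col] if effects in ("unit", "unit+time") else []) + \
               ([time_col] if effects in ("time", "unit+time") else []):
        sizes = df.groupby(key)[key].transform("size")
        if (sizes == 1).any():
            dropped = df.loc[sizes == 1, key].unique().tolist()
            warnings.warn(f"dropping singleton {key} groups: {dropped}")
            df = df[sizes > 1].reset_index(drop=True)
    cols = list(columns)
    vals = df[cols].to_numpy(float)
    u_codes = pd.factorize(df[unit_col])[0]
    t_codes = pd.factorize(df[time_col])[0]

    def _demean(codes: np.ndarray, x: np.ndarray) -> np.ndarray:
        sums = np.zeros((codes.max() + 1, x.shape[1]))
        np.add.at(sums, codes, x)
        counts = np.bincount(codes).astype(float)[:, None]
        return x - (sums / counts)[codes]

    if effects == "unit":
        vals = _demean(u_codes, vals)
    elif effects == "time":
        vals = _demean(t_codes, vals)
    else:
        for _ in range(max_iter):
            vals = _demean(u_codes, vals)
            vals = _demean(t_codes, vals)
            usum = np.zeros((u_codes.max() + 1, vals.shape[1]))
            np.add.at(usum, u_codes, vals)
            umean = usum / np.bincount(u_codes)[:, None]
            if np.abs(umean).max() < tol:
                break
        else:  # pragma: no cover - pathological panels
            raise RuntimeError("within transform failed to converge")
    out = df.copy()
    out[cols] = vals
    return out


def _absorbed_df(effects: Effects, n_units: int, n_times: int) -> int:
    return {"none": 0, "unit": n_units, "time": n_times,
            "unit+time": n_units + n_times - 1}[effects]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [nm for j, nm in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise RankDeficientError(f"design is rank deficient; collinear columns: {bad}")


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


# ---------------------------------------------------------------------------
# covariance estimators
# ---------------------------------------------------------------------------

def driscoll_kraay_cov(
    X: np.ndarray,
    resid: np.ndarray,
    times: np.ndarray,
    df_resid: int,
    bandwidth: Optional[int] = None,
) -> np.ndarray:
    """Kernel covariance robust to heteroscedasticity, serial and
    cross-sectional correlation.

    Moment vectors are summed across units per period, h_t = sum_i x_it e_it,
    and smoothed over time lags with a Bartlett kernel.  Default lag window
    is floor(4 (T/100)^(2/9)) + 1.
    """
    periods, t_codes = np.unique(times, return_inverse=True)
    T = len(periods)
    if T < 3:
        raise ValueError("need at least 3 periods for the kernel covariance")
    k = X.shape[1]
    h = np.zeros((T, k))
    np.add.at(h, t_codes, X * resid[:, None])
    m = bandwidth if bandwidth is not None else int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0))) + 1
    S = h.T @ h
    for j in range(1, min(m, T - 1) + 1):
        w = 1.0 - j / (m + 1.0)
        gamma = h[j:].T @ h[:-j]
        S += w * (gamma + gamma.T)
    xtx_inv = np.linalg.inv(X.T @ X)
    n = X.shape[0]
    adj = n / max(df_resid, 1)
    V = adj * xtx_inv @ S @ xtx_inv
    return (V + V.T) / 2.0


def cluster_cov(X: np.ndarray, resid: np.ndarray, units: np.ndarray,
                df_resid: int) -> np.ndarray:
    """Cluster-robust (by unit) sandwich covariance."""
    groups, codes = np.unique(units, return_inverse=True)
    k = X.shape[1]
    S = np.zeros((k, k))
    xe = X * resid[:, None]
    for g in range(len(groups)):
        hg = xe[codes == g].sum(axis=0)
        S += np.outer(hg, hg)
    G = len(groups)
    n = X.shape[0]
    adj = (G / (G - 1)) * ((n - 1) / max(df_resid, 1))
    xtx_inv = np.linalg.inv(X.T @ X)
    V = adj * xtx_inv @ S @ xtx_inv
    return (V + V.T) / 2.0


def _covariance(cov_type: str, X, resid, units, times, df_resid, s2):
    if cov_type == "classical":
        return s2 * np.linalg.inv(X.T @ X)
    if cov_type == "robust_3way":
        return driscoll_kraay_cov(X, resid, times, df_resid)
    if cov_type == "cluster":
        return cluster_cov(X, resid, units, df_resid)
    raise ValueError(f"unknown covariance type {cov_type!r}")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def fit_panel(
    spec: ModelSpec,
    panel: pd.DataFrame,
    estimator: Literal["pooled", "fe", "re"] = "fe",
) -> PanelFitResult:
    """Fit one panel model.

    * ``fe``: OLS on within-transformed data (per ``spec.effects``) with a
      degrees-of-freedom correction for the absorbed effects; point
      estimates identical to dummy-variable OLS.
    * ``re``: Swamy-Arora feasible GLS with unit random effects
      (quasi-demeaning); time effects, when requested, enter as dummies.
    * ``pooled``: plain OLS with a constant.
    """
    missing = [v for v in (spec.dependent, *spec.regressors)
               if v not in panel.columns]
    if missing:
        raise KeyError(f"variables missing from panel: {missing}")
    df = panel.dropna(subset=[spec.dependent, *spec.regressors])
    df = df.sort_values([spec.unit_col, spec.time_col]).reset_index(drop=True)
    y_orig = df[spec.dependent].to_numpy(float)
    units = df[spec.unit_col].to_numpy()
    times = df[spec.time_col].to_numpy()
    n_units = len(np.unique(units))
    n_times = len(np.unique(times))
    names = list(spec.regressors)

    if estimator == "fe":
        cols = [spec.dependent, *spec.regressors]
        tdf = within_transform(df, cols, spec.effects, spec.unit_col, spec.time_col)
        X = tdf[names].to_numpy(float)
        y = tdf[spec.dependent].to_numpy(float)
        units = tdf[spec.unit_col].to_numpy()
        times = tdf[spec.time_col].to_numpy()
        _check_rank(X, names)
        beta, resid = _ols(X, y)
        absorbed = _absorbed_df(spec.effects, n_units, n_times)
        df_resid = len(y) - len(names) - absorbed
        fitted_partial = X @ beta
        r2_within = 1.0 - (resid @ resid) / (y @ y) if y @ y > 0 else 0.0
        xb = df[names].to_numpy(float) @ beta
        r2_overall = _sq_corr(xb, y_orig)
    elif estimator == "pooled":
        names = ["const", *spec.regressors]
        X = np.column_stack([np.ones(len(df)), df[list(spec.regressors)].to_numpy(float)])
        y = y_orig
        _check_rank(X, names)
        beta, resid = _ols(X, y)
        df_resid = len(y) - len(names)
        fitted_partial = X @ beta
        r2_within = r2_overall = _sq_corr(fitted_partial, y)
    elif estimator == "re":
        return _fit_re(spec, df)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    if df_resid <= 0:
        raise ValueError("not enough observations for the requested model")
    s2 = (resid @ resid) / df_resid
    V = _covariance(spec.cov, X, resid, units, times, df_resid, s2)
    se = np.sqrt(np.diag(V))
    return PanelFitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        std_errors=pd.Series(se, index=names),
        nobs=len(y),
        df_resid=df_resid,
        resid=resid,
        fitted=fitted_partial,
        r2_within=float(r2_within),
        r2_overall=float(r2_overall),
        ssr=float(resid @ resid),
        estimator=estimator,
        effects=spec.effects,
        cov_type=spec.cov,
    )


def _sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _fit_re(spec: ModelSpec, df: pd.DataFrame) -> PanelFitResult:
    """Swamy-Arora random effects via quasi-demeaning (unit effects random;
    time effects as dummies when the spec asks for them)."""
    unit_col, time_col = spec.unit_col, spec.time_col
    names = list(spec.regressors)
    times_all = np.sort(df[time_col].unique())
    dummy_names: list[str] = []
    work = df.copy()
    if spec.effects in ("time", "unit+time"):
        for t in times_all[1:]:
            nm = f"_d{t}"
            work[nm] = (work[time_col] == t).astype(float)
            dummy_names.append(nm)
    regs = names + dummy_names

    # variance components from within and between regressions
    wdf = within_transform(work, [spec.dependent, *regs], "unit",
                           unit_col, time_col)
    Xw = wdf[regs].to_numpy(float)
    yw = wdf[spec.dependent].to_numpy(float)
    keep = [j for j in range(Xw.shape[1]) if Xw[:, j].std() > 0]
    bw, rw = _ols(Xw[:, keep], yw)
    n_units = work[unit_col].nunique()
    sigma_e2 = (rw @ rw) / (len(yw) - n_units - len(keep))
    means = work.groupby(unit_col)[[spec.dependent, *regs]].mean()
    Xb = np.column_stack([np.ones(len(means)), means[regs].to_numpy(float)])
    yb = means[spec.dependent].to_numpy(float)
    keep_b = [0] + [1 + j for j in range(len(regs))
                    if means[regs].to_numpy(float)[:, j].std() > 0]
    bb, rb = _ols(Xb[:, keep_b], yb)
    df_b = len(means) - len(keep_b)
    t_bar = len(work) / n_units
    s_between2 = (rb @ rb) / max(df_b, 1)
    sigma_u2 = max(0.0, s_between2 - sigma_e2 / t_bar)
    theta = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + t_bar * sigma_u2))

    umeans = work.groupby(unit_col)[[spec.dependent, *regs]].transform("mean")
    y = (work[spec.dependent] - theta * umeans[spec.dependent]).to_numpy(float)
    X = (work[regs] - theta * umeans[regs]).to_numpy(float)
    const = np.full((len(work), 1), 1.0 - theta)
    X = np.hstack([const, X])
    all_names = ["const", *regs]
    _check_rank(X, all_names)
    beta, resid = _ols(X, y)
    df_resid = len(y) - X.shape[1]
    s2 = (resid @ resid) / df_resid
    units = work[unit_col].to_numpy()
    times = work[time_col].to_numpy()
    V = _covariance(spec.cov, X, resid, units, times, df_resid, s2)
    se = np.sqrt(np.diag(V))
    xb = X @ beta
    res = PanelFitResult(
        params=pd.Series(beta, index=all_names),
        cov=pd.DataFrame(V, index=all_names, columns=all_names),
        std_errors=pd.Series(se, index=all_names),
        nobs=len(y),
        df_resid=df_resid,
        resid=resid,
        fitted=xb,
        r2_within=_sq_corr(Xw[:, keep] @ bw, yw),
        r2_overall=_sq_corr(xb, work[spec.dependent].to_numpy(float)),
        ssr=float(resid @ resid),
        estimator="re",
        effects=spec.effects,
        cov_type=spec.cov,
    )
    res.diagnostics["variance_components"] = {
        "sigma_e2": float(sigma_e2), "sigma_u2": float(sigma_u2),
        "theta": float(theta),
    }
    return res


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def hausman_test(fe_fit: PanelFitResult, re_fit: PanelFitResult):
    """Hausman specification test on the coefficients both models share.

    H = (b_fe - b_re)' (V_fe - V_re)^+ (b_fe - b_re), chi-square with
    df = rank(V_fe - V_re).  A pseudo-inverse guards against the frequently
    indefinite variance difference in small panels.
    """
    common = [c for c in fe_fit.params.index
              if c in re_fit.params.index and not c.startswith("_d")
              and c != "const"]
    if not common:
        raise ValueError("no overlapping coefficients between the two fits")
    d = (fe_fit.params[common] - re_fit.params[common]).to_numpy()
    V = (fe_fit.cov.loc[common, common].to_numpy()
         - re_fit.cov.loc[common, common].to_numpy())
    if np.allclose(d, 0.0):
        return 0.0, len(common), 1.0
    Vp = np.linalg.pinv(V, rcond=1e-12)
    H = float(max(d @ Vp @ d, 0.0))
    df_ = int(np.linalg.matrix_rank(V, tol=1e-12))
    df_ = max(df_, 1)
    return H, df_, float(stats.chi2.sf(H, df_))


def poolability_ftest(panel: pd.DataFrame, spec: ModelSpec):
    """F test of pooled OLS against the unit-dummy (fixed-effects) model."""
    units = panel[spec.unit_col].unique()
    if len(units) < 2:
        raise ValueError("poolability test needs at least two units")
    df = panel.dropna(subset=[spec.dependent, *spec.regressors])
    y = df[spec.dependent].to_numpy(float)
    Xp = np.column_stack([np.ones(len(df)), df[list(spec.regressors)].to_numpy(float)])
    _, resid_p = _ols(Xp, y)
    wdf = within_transform(df, [spec.dependent, *spec.regressors], "unit",
                           spec.unit_col, spec.time_col)
    Xf = wdf[list(spec.regressors)].to_numpy(float)
    _, resid_f = _ols(Xf, wdf[spec.dependent].to_numpy(float))
    n_units = df[spec.unit_col].nunique()
    k = len(spec.regressors)
    ssr_p = resid_p @ resid_p
    ssr_f = resid_f @ resid_f
    df1 = n_units - 1
    df2 = len(df) - n_units - k
    F = ((ssr_p - ssr_f) / df1) / (ssr_f / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_k) per column.

    An (effectively) duplicated column is reported as ``inf``.
    """
    X = design.to_numpy(float)
    out = {}
    for j, name in enumerate(design.columns):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - (resid @ resid) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# 2SLS with the lagged key regressor as instrument
# ---------------------------------------------------------------------------

def fit_2sls(
    spec: ModelSpec,
    panel: pd.DataFrame,
    instrument: Optional[str] = None,
) -> PanelFitResult:
    """Within-transformed two-stage least squares.

    The key regressor is treated as endogenous and instrumented by its
    one-period lag within unit (default) or by a named column.  One period is
    lost to the lag, so a balanced N x T input yields N x (T-1)
    observations.  The result carries the first-stage coefficient on the
    excluded instrument and the first-stage F; a first-stage F below 10
    triggers a weak-instrument warning (not a failure).
    """
    df = panel.sort_values([spec.unit_col, spec.time_col]).reset_index(drop=True).copy()
    if instrument is None:
        instrument = f"{spec.key_regressor}_lag1"
        df[instrument] = df.groupby(spec.unit_col)[spec.key_regressor].shift(1)
    df = df.dropna(subset=[spec.dependent, instrument, *spec.regressors])
    df = df.reset_index(drop=True)
    n_units = df[spec.unit_col].nunique()
    n_times = df[spec.time_col].nunique()

    cols = [spec.dependent, spec.key_regressor, instrument, *spec.controls]
    tdf = within_transform(df, cols, spec.effects, spec.unit_col, spec.time_col)
    y = tdf[spec.dependent].to_numpy(float)
    x = tdf[spec.key_regressor].to_numpy(float)
    z = tdf[instrument].to_numpy(float)
    W = tdf[list(spec.controls)].to_numpy(float) if spec.controls else np.empty((len(y), 0))

    # first stage: x on [z, controls]
    Z1 = np.column_stack([z, W]) if W.size else z[:, None]
    b1, r1 = _ols(Z1, x)
    absorbed = _absorbed_df(spec.effects, n_units, n_times)
    df1 = len(y) - Z1.shape[1] - absorbed
    s2_1 = (r1 @ r1) / df1
    se1 = np.sqrt(s2_1 * np.linalg.inv(Z1.T @ Z1)[0, 0])
    f_first = float((b1[0] / se1) ** 2)
    if f_first < 10.0:
        warnings.warn(f"weak instrument: first-stage F = {f_first:.2f} < 10")

    x_hat = Z1 @ b1
    X2 = np.column_stack([x_hat, W]) if W.size else x_hat[:, None]
    names = [spec.key_regressor, *spec.controls]
    _check_rank(X2, names)
    beta, _ = _ols(X2, y)
    # structural residuals use the actual endogenous regressor
    X_act = np.column_stack([x, W]) if W.size else x[:, None]
    resid = y - X_act @ beta
    df_resid = len(y) - X2.shape[1] - absorbed
    s2 = (resid @ resid) / df_resid
    V = s2 * np.linalg.inv(X2.T @ X2)
    se = np.sqrt(np.diag(V))
    res = PanelFitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        std_errors=pd.Series(se, index=names),
        nobs=len(y),
        df_resid=df_resid,
        resid=resid,
        fitted=X_act @ beta,
        r2_within=_sq_corr(X_act @ beta, y),
        r2_overall=_sq_corr(df[list(names)].to_numpy(float) @ beta,
                            df[spec.dependent].to_numpy(float)),
        ssr=float(resid @ resid),
        estimator="2sls",
        effects=spec.effects,
        cov_type="classical",
    )
    res.diagnostics["first_stage"] = {
        "coefficient": float(b1[0]),
        "se": float(se1),
        "F": f_first,
        "instrument": instrument,
    }
    return res
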