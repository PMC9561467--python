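"""Synthetic provincial / prefecture panels with known ground truth.

The generator emulates the statistical structure of a hand-collected Chinese
provincial health-resource panel: 22 provinces observed over 10 years, each
province containing 5-21 prefecture-level cities.  The province-level
data-generating process is the additive two-way fixed-effects model

    THEIL_it = alpha + beta * FASG_it + sum_l delta_l X_lit + phi_i + omega_t + eps_it

run forward, optionally replaced by the regime-switching analogue in which the
FASG coefficient changes when a threshold variable crosses gamma.  Covariate
marginal moments default to the observed provincial means/SDs (FASG
0.4820/0.1597, PGDP 10.6344/0.3669, PD 5.4740/0.8721, TA 3.6242/1.4012, DR
0.3811/0.0705, IR 0.0415/0.0195); PGDP, PD and AHRH live on the natural-log
scale, which is what magnitudes like a PGDP mean of 10.63 imply.

FASG follows a stationary AR(1) path (persistence 0.8, clipped to (0.05,
0.95)) so that its one-year lag is a relevant instrument, mirroring the
lag-IV design of the analysis layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DGPConfig",
    "MediatorSpec",
    "ThresholdDGP",
    "GroundTruth",
    "gen_province_panel",
    "gen_prefecture_resources",
    "inject_missingness",
    "RESOURCE_COLUMNS",
    "DEFAULT_COVARIATE_MOMENTS",
]

# Marginal (mean, SD) of each provincial covariate in the emulated panel.
DEFAULT_COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "FASG": (0.4820, 0.1597),
    "PGDP": (10.6344, 0.3669),
    "PD": (5.4740, 0.8721),
    "TA": (3.6242, 1.4012),
    "DR": (0.3811, 0.0705),
    "IR": (0.0415, 0.0195),
}

#: marginal moments of the two mediators and the index variants
_MEDIATOR_MOMENTS = {"IGHE": (0.3058, 0.0632), "AHRH": (12.2909, 0.6357)}
_ALT_INDEX_MOMENTS = {"CV": (0.0895, 0.0288), "GINI": (0.1883, 0.0494)}

#: extra provincial expenditure/output shares used by the robustness stage
#: (tertiary-industry share of GDP, public-service and education shares of
#: fiscal expenditure); independent of FASG by construction.
EXTRA_CONTROL_MOMENTS = {"SERV": (0.46, 0.06), "PUBS": (0.18, 0.04), "EDU": (0.16, 0.03)}

RESOURCE_COLUMNS = ("n_institutions", "n_beds", "n_doctors", "n_nurses")

_FASG_RHO = 0.80          # AR(1) persistence of the fiscal-autonomy path
_FASG_BOUNDS = (0.05, 0.95)
_CONTROL_RHO = 0.50       # mild persistence for the control covariates


class ConfigError(ValueError):
    """Invalid data-generating configuration."""


@dataclass(frozen=True)
class ThresholdDGP:
    """Regime-switching component: FASG coefficient flips at each gamma.

    ``betas`` has one more entry than ``gammas`` (one coefficient per regime,
    regimes ordered from the lowest values of the threshold variable up).
    """

    variable: str = "DR"
    gammas: tuple[float, ...] = (0.4640,)
    betas: tuple[float, ...] = (-0.0729, -0.0981)

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.gammas) + 1:
            raise ConfigError("need len(betas) == len(gammas) + 1")
        if list(self.gammas) != sorted(self.gammas):
            raise ConfigError("gammas must be sorted ascending")


@dataclass(frozen=True)
class MediatorSpec:
    """Effects of FASG on the two mediating channels."""

    ighe_effect: float = 0.0474   # government share of total health expenditure
    ahrh_effect: float = 0.1079   # log health workforce (doctors + nurses)


@dataclass(frozen=True)
class DGPConfig:
    n_provinces: int = 22
    n_years: int = 10
    cities_per_province: tuple[int, int] = (5, 21)
    beta_fasg: float = -0.0849
    alpha: float = 0.1391
    control_effects: dict = field(
        default_factory=lambda: {
            "PGDP": -0.0010,
            "PD": 0.0123,
            "TA": -0.0129,
            "DR": -0.0980,
            "IR": 0.1913,
        }
    )
    threshold_spec: Optional[ThresholdDGP] = None
    mediator_spec: Optional[MediatorSpec] = field(default_factory=MediatorSpec)
    sigma_eps: float = 0.010
    fe_sd: tuple[float, float] = (0.050, 0.005)  # (province, year) effect SDs
    covariate_moments: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MOMENTS))
    start_year: int = 2011
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 2:
            raise ConfigError("n_provinces must be >= 2")
        if self.n_years < 3:
            raise ConfigError("n_years must be >= 3")
        lo, hi = self.cities_per_province
        if not (1 <= lo <= hi):
            raise ConfigError("invalid cities_per_province range")
        if self.sigma_eps < 0 or any(s < 0 for s in self.fe_sd):
            raise ConfigError("noise / fixed-effect SDs must be >= 0")
        for name, (_, sd) in self.covariate_moments.items():
            if sd < 0:
                raise ConfigError(f"negative SD configured for {name}")
        if self.threshold_spec is not None:
            if self.threshold_spec.variable not in self.covariate_moments:
                raise ConfigError(
                    f"threshold variable {self.threshold_spec.variable!r} has no "
                    "configured moments"
                )


@dataclass
class GroundTruth:
    """Every drawn effect of one generated panel, for recovery tests."""

    beta_fasg: float
    alpha: float
    control_effects: dict
    province_effects: np.ndarray
    year_effects: np.ndarray
    threshold_spec: Optional[ThresholdDGP]
    mediator_spec: Optional[MediatorSpec]
    sigma_eps: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy (parameter, value) table for the sidecar file."""
        rows = [("beta_fasg", self.beta_fasg), ("alpha", self.alpha),
                ("sigma_eps", self.sigma_eps), ("seed", self.seed)]
        rows += [(f"delta_{k}", v) for k, v in self.control_effects.items()]
        rows += [(f"phi_{i}", v) for i, v in enumerate(self.province_effects, 1)]
        rows += [(f"omega_{t}", v) for t, v in enumerate(self.year_effects)]
        if self.threshold_spec is not None:
            ts = self.threshold_spec
            rows += [(f"gamma_{j + 1}", g) for j, g in enumerate(ts.gammas)]
            rows += [(f"beta_regime_{j + 1}", b) for j, b in enumerate(ts.betas)]
            rows.append(("threshold_variable", ts.variable))
        if self.mediator_spec is not None:
            rows += [("effect_IGHE", self.mediator_spec.ighe_effect),
                     ("effect_AHRH", self.mediator_spec.ahrh_effect)]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def _ar1_paths(rng: np.random.Generator, n: int, t: int, mean: float, sd: float,
               rho: float) -> np.ndarray:
    """Stationary AR(1) with the requested *marginal* mean/SD, shape (n, t)."""
    x = np.empty((n, t))
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    x[:, 0] = mean + sd * rng.standard_normal(n)
    for k in range(1, t):
        x[:, k] = mean + rho * (x[:, k - 1] - mean) + innov_sd * rng.standard_normal(n)
    return x


def gen_province_panel(config: DGPConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the province-year regression panel plus its ground truth.

    Returns a balanced panel with columns ``province_id, year, THEIL, CV,
    GINI, FASG, IGHE, AHRH, PGDP, PD, TA, DR, IR, SERV, PUBS, EDU``.  The CV
    and GINI columns are noisy monotone companions of THEIL (rank correlation
    ~0.9) standing in for the alternative index constructions used as
    robustness dependent variables.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_provinces, config.n_years
    years = np.arange(config.start_year, config.start_year + t)

    covs: dict[str, np.ndarray] = {}
    fasg_mean, fasg_sd = config.covariate_moments["FASG"]
    fasg = _ar1_paths(rng, n, t, fasg_mean, fasg_sd, _FASG_RHO)
    covs["FASG"] = np.clip(fasg, *_FASG_BOUNDS)
    for name, (mean, sd) in config.covariate_moments.items():
        if name == "FASG":
            continue
        covs[name] = _ar1_paths(rng, n, t, mean, sd, _CONTROL_RHO)
    # DR and IR are population shares; keep them positive
    for name in ("DR", "IR"):
        if name in covs:
            covs[name] = np.clip(covs[name], 1e-4, None)

    phi = config.fe_sd[0] * rng.standard_normal(n)
    omega = config.fe_sd[1] * rng.standard_normal(t)
    eps = config.sigma_eps * rng.standard_normal((n, t))

    effects = dict(config.control_effects)
    ts = config.threshold_spec
    if ts is None:
        signal = config.beta_fasg * covs["FASG"]
    else:
        # estimating equation omits the threshold variable from the controls,
        # so its own linear effect is switched off in threshold mode
        effects[ts.variable] = 0.0
        q = covs[ts.variable]
        edges = (-np.inf,) + ts.gammas + (np.inf,)
        signal = np.zeros_like(q)
        for b, lo, hi in zip(ts.betas, edges[:-1], edges[1:]):
            signal += b * covs["FASG"] * ((q > lo) & (q <= hi))
    index = (config.alpha + signal
             + sum(d * covs[v] for v, d in effects.items() if v in covs)
             + phi[:, None] + omega[None, :] + eps)

    # alternative-index companions: shared rank structure, own scale + noise
    t_mean, t_sd = float(index.mean()), float(index.std()) or 1.0
    z = (index - t_mean) / t_sd
    r = 0.9
    alt: dict[str, np.ndarray] = {}
    for name, (mean, sd) in _ALT_INDEX_MOMENTS.items():
        noise = rng.standard_normal((n, t))
        alt[name] = mean + sd * (r * z + np.sqrt(1 - r**2) * noise)

    med = config.mediator_spec
    mediators: dict[str, np.ndarray] = {}
    if med is not None:
        for name, eff, fe_i, fe_t, s_e in (
            ("IGHE", med.ighe_effect, 0.040, 0.005, 0.015),
            ("AHRH", med.ahrh_effect, 0.600, 0.010, 0.020),
        ):
            mean, _ = _MEDIATOR_MOMENTS[name]
            m = (mean + eff * (covs["FASG"] - fasg_mean)
                 + fe_i * rng.standard_normal(n)[:, None]
                 + fe_t * rng.standard_normal(t)[None, :]
                 + s_e * rng.standard_normal((n, t)))
            mediators[name] = np.clip(m, 1e-3, 1 - 1e-3) if name == "IGHE" else m

    extras = {name: np.clip(mean + sd * rng.standard_normal((n, t)), 1e-3, 1 - 1e-3)
              for name, (mean, sd) in EXTRA_CONTROL_MOMENTS.items()}

    prov = np.repeat(np.arange(1, n + 1), t)
    cols: dict[str, np.ndarray] = {
        "province_id": prov,
        "year": np.tile(years, n),
        "THEIL": index.ravel(),
    }
    for name in ("CV", "GINI"):
        cols[name] = alt[name].ravel()
    cols["FASG"] = covs["FASG"].ravel()
    for name in mediators:
        cols[name] = mediators[name].ravel()
    for name in config.covariate_moments:
        if name != "FASG":
            cols[name] = covs[name].ravel()
    for name in extras:
        cols[name] = extras[name].ravel()
    panel = pd.DataFrame(cols)

    truth = GroundTruth(
        beta_fasg=config.beta_fasg,
        alpha=config.alpha,
        control_effects=effects,
        province_effects=phi,
        year_effects=omega,
        threshold_spec=ts,
        mediator_spec=med,
        sigma_eps=config.sigma_eps,
        seed=config.seed,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# prefecture-level resource counts
# ---------------------------------------------------------------------------

#: per-capita / per-km2 base rates of the four resource indicators
#: (institutions per km2; beds, doctors, nurses per person)
_BASE_RATES = {
    "n_institutions": 0.08,
    "n_beds": 0.0060,
    "n_doctors": 0.0029,
    "n_nurses": 0.0033,
}


def gen_prefecture_resources(
    config: DGPConfig,
    inequality_driver,
) -> pd.DataFrame:
    """Generate city-year resource counts whose within-province dispersion
    is controlled per province-year.

    ``inequality_driver`` is either a scalar (one log-scale dispersion SD for
    every province-year) or a DataFrame with columns ``province_id, year,
    dispersion``.  City log per-capita (per-km2 for institutions) rates are
    drawn around a province-year mean with SD equal to the driver, so the
    Theil index of the output increases with the driver in expectation
    (for lognormal rates, Theil ~= sigma^2 / 2).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n, t = config.n_provinces, config.n_years
    years = np.arange(config.start_year, config.start_year + t)

    if np.isscalar(inequality_driver):
        disp = np.full((n, t), float(inequality_driver))
    else:
        d = pd.DataFrame(inequality_driver).pivot(
            index="province_id", columns="year", values="dispersion"
        )
        disp = d.reindex(index=np.arange(1, n + 1), columns=years).to_numpy(float)
        if np.isnan(disp).any():
            raise ConfigError("inequality_driver does not cover every province-year")
    if (disp < 0).any():
        raise ConfigError("dispersion values must be >= 0")

    lo, hi = config.cities_per_province
    n_cities = rng.integers(lo, hi + 1, size=n)

    rows = []
    for i in range(n):
        m = n_cities[i]
        # city size/geography fixed over time
        population = np.exp(rng.normal(np.log(3.5e6), 0.5, size=m))
        land_area = np.exp(rng.normal(np.log(1.2e4), 0.5, size=m))
        # province-year mean log rates wobble mildly around the base rates
        for k, year in enumerate(years):
            base = {c: np.log(r) + 0.05 * rng.standard_normal()
                    for c, r in _BASE_RATES.items()}
            sigma = disp[i, k]
            rec: dict[str, np.ndarray] = {}
            for col in RESOURCE_COLUMNS:
                log_rate = base[col] + sigma * rng.standard_normal(m)
                denom = land_area if col == "n_institutions" else population
                rec[col] = np.rint(np.exp(log_rate) * denom)
            for j in range(m):
                rows.append({
                    "province_id": i + 1,
                    "city_id": j + 1,
                    "year": year,
                    **{c: rec[c][j] for c in RESOURCE_COLUMNS},
                    "population": population[j],
                    "land_area": land_area[j],
                })
    panel = pd.DataFrame(rows)
    if (panel["population"] <= 0).any() or (panel["land_area"] <= 0).any():
        raise ConfigError("non-positive population or land area generated")
    return panel


def inject_missingness(
    panel: pd.DataFrame,
    rate: float,
    pattern: str = "internal",
    seed: int = 0,
) -> pd.DataFrame:
    """Blank exactly ``floor(rate * n_cells)`` resource cells.

    A "cell" is one of the four resource-count entries of one city-year row.
    ``pattern='internal'`` never blanks a city's first or last observed year
    (so linear interpolation always has two neighbours); ``pattern='edge'``
    blanks only first/last years (exercising the geometric-growth
    extrapolation rule).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if pattern not in ("internal", "edge"):
        raise ValueError("pattern must be 'internal' or 'edge'")
    out = panel.copy()
    n_cells = len(out) * len(RESOURCE_COLUMNS)
    n_blank = int(np.floor(rate * n_cells))
    if n_blank == 0:
        return out

    grp = out.groupby(["province_id", "city_id"])["year"]
    first = grp.transform("min")
    last = grp.transform("max")
    is_edge = (out["year"] == first) | (out["year"] == last)
    eligible_rows = np.flatnonzero(is_edge if pattern == "edge" else ~is_edge)
    cells = [(r, c) for r in eligible_rows for c in RESOURCE_COLUMNS]
    if n_blank > len(cells):
        raise ValueError(
            f"cannot blank {n_blank} cells: only {len(cells)} eligible under "
            f"pattern={pattern!r}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(cells), size=n_blank, replace=False)
    for col in RESOURCE_COLUMNS:
        out[col] = out[col].astype(float)
    for idx in picked:
        r, c = cells[idx]
        out.iloc[r, out.columns.get_loc(c)] = np.nan
    return out
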