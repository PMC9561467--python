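"""Within-province equity indices of healthcare resource allocation.

Pipeline: fill missing yearly counts (linear interpolation inside a city's
series, geometric-mean growth extrapolation at the edges), normalize the four
raw indicators by geography/population (institutions per km2; beds, doctors,
nurses per 1,000 people), compute an inequality index of each indicator
across the cities of a province-year, and combine the four indices with
entropy weights into one composite EHRA value per province-year.  Smaller
composite = more equitable allocation.

Inequality measures (y_i = city value, ybar = mean over the n cities):

    Theil  T = (1/n) sum (y_i/ybar) ln(y_i/ybar)       (Theil-T, natural log)
    CV       = population SD / mean
    Gini   G = sum_ij |y_i - y_j| / (2 n^2 ybar)

All three are zero under perfect equality, nonnegative, and invariant to a
common rescaling of the values.  Cities are weighted equally (1/n), not by
population.  Entropy weights are computed once on the pooled province-year
matrix of per-indicator index values so the composite is comparable across
provinces and years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import RESOURCE_COLUMNS

__all__ = [
    "UnfillableSeriesError",
    "UndefinedIndexError",
    "fill_missing",
    "fill_panel",
    "normalize_indicators",
    "theil",
    "cv",
    "gini",
    "entropy_weights",
    "compose_ehra",
    "EquityIndexSet",
]

logger = logging.getLogger(__name__)

INDICATORS = ("inst_per_km2", "beds_per_1000", "docs_per_1000", "nurses_per_1000")


class UnfillableSeriesError(ValueError):
    """Fewer than two observed values: nothing to interpolate from."""


class UndefinedIndexError(ValueError):
    """Inequality index undefined (all-zero or negative input)."""


# ---------------------------------------------------------------------------
# missing-data fill rules
# ---------------------------------------------------------------------------

def fill_missing(series: pd.Series) -> pd.Series:
    """Complete a yearly series with interior interpolation + edge growth.

    Interior gaps are filled linearly between the nearest observed
    neighbours.  Leading/trailing gaps are extrapolated with the geometric
    mean g of the observed year-over-year growth ratios: the first observed
    value is divided by g per step backwards, the last multiplied by g per
    step forwards.  Observed values are never touched.  If any observed value
    is non-positive while edge extrapolation is needed, the nearest observed
    value is carried instead (with a warning), since growth ratios are then
    undefined.
    """
    s = pd.Series(series).astype(float)
    years = np.asarray(s.index, dtype=float)
    if np.any(np.diff(years) <= 0):
        order = np.argsort(years)
        s = s.iloc[order]
        years = years[order]
    vals = s.to_numpy()
    obs = ~np.isnan(vals)
    if obs.sum() < 2:
        raise UnfillableSeriesError(
            f"need >= 2 observed values, got {int(obs.sum())}"
        )
    out = np.interp(years, years[obs], vals[obs])  # interior + flat edges
    first, last = np.flatnonzero(obs)[[0, -1]]

    if first > 0 or last < len(vals) - 1:
        inner = out[first:last + 1]
        if np.any(vals[obs] <= 0):
            logger.warning(
                "non-positive observed values: edge gaps carried from the "
                "nearest observation instead of geometric extrapolation"
            )
        else:
            # geometric mean of year-over-year ratios of the completed
            # interior series
            steps = np.diff(years[first:last + 1])
            ratios = (inner[1:] / inner[:-1]) ** (1.0 / steps)
            g = float(np.exp(np.mean(np.log(ratios))))
            for k in range(first - 1, -1, -1):
                out[k] = out[k + 1] / g ** (years[k + 1] - years[k])
            for k in range(last + 1, len(vals)):
                out[k] = out[k - 1] * g ** (years[k] - years[k - 1])
    out[obs] = vals[obs]
    return pd.Series(out, index=s.index, name=s.name)


def fill_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`fill_missing` to every city's resource series with gaps."""
    out = panel.sort_values(["province_id", "city_id", "year"]).reset_index(drop=True)
    for col in RESOURCE_COLUMNS:
        if not out[col].isna().any():
            continue
        filled = (
            out.set_index("year")
            .groupby(["province_id", "city_id"], group_keys=False)[col]
            .apply(fill_missing)
        )
        out[col] = filled.to_numpy()
    return out


# ---------------------------------------------------------------------------
# indicator normalization
# ---------------------------------------------------------------------------

def normalize_indicators(panel: pd.DataFrame) -> pd.DataFrame:
    """Scale raw counts into per-km2 / per-1,000-person indicator rates."""
    bad = panel[(panel["population"] <= 0) | (panel["land_area"] <= 0)]
    if len(bad):
        key = bad.iloc[0]
        raise ValueError(
            "non-positive population or land area at "
            f"(province={key['province_id']}, city={key['city_id']}, "
            f"year={key['year']})"
        )
    out = panel[["province_id", "city_id", "year"]].copy()
    out["inst_per_km2"] = panel["n_institutions"] / panel["land_area"]
    out["beds_per_1000"] = 1000.0 * panel["n_beds"] / panel["population"]
    out["docs_per_1000"] = 1000.0 * panel["n_doctors"] / panel["population"]
    out["nurses_per_1000"] = 1000.0 * panel["n_nurses"] / panel["population"]
    return out


# ---------------------------------------------------------------------------
# scalar inequality measures
# ---------------------------------------------------------------------------

def _check_values(values) -> np.ndarray:
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        raise UndefinedIndexError("empty vector")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise UndefinedIndexError("values must be finite and nonnegative")
    if not np.any(y > 0):
        raise UndefinedIndexError("all-zero vector: index undefined")
    return y


def theil(values) -> float:
    """Theil-T index, natural log, 0*ln(0) = 0."""
    y = _check_values(values)
    share = y / y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(share > 0, share * np.log(share), 0.0)
    return float(terms.mean())


def cv(values) -> float:
    """Coefficient of variation: population SD over the mean."""
    y = _check_values(values)
    return float(y.std(ddof=0) / y.mean())


def gini(values) -> float:
    """Gini coefficient via the sorted-rank formula (O(n log n))."""
    y = np.sort(_check_values(values))
    n = y.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * y)) / (n * np.sum(y)) - (n + 1.0) / n)


_MEASURES = {"theil": theil, "cv": cv, "gini": gini}


# ---------------------------------------------------------------------------
# entropy weighting and composite
# ---------------------------------------------------------------------------

def entropy_weights(index_matrix) -> np.ndarray:
    """Objective column weights from information entropy.

    For column j with entries x_ij >= 0 over m rows: p_ij = x_ij / sum_i
    x_ij, e_j = -(1/ln m) sum_i p_ij ln p_ij (0*ln 0 = 0), and w_j
    proportional to 1 - e_j.  Low-entropy (more informative) columns get
    larger weight; a constant column carries no information and gets weight
    0.  If every column is constant the weights fall back to equal shares.
    """
    x = np.asarray(index_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("entries must be finite and nonnegative")
    m = x.shape[0]
    totals = x.sum(axis=0)
    d = np.zeros(x.shape[1])
    for j, total in enumerate(totals):
        if total <= 0:
            continue  # zero column: no information, d stays 0
        p = x[:, j] / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum() / np.log(m)
        d[j] = 1.0 - e
    if d.sum() <= 1e-12:
        logger.warning("all columns constant: falling back to equal weights")
        return np.full(x.shape[1], 1.0 / x.shape[1])
    return d / d.sum()


@dataclass
class EquityIndexSet:
    """Per province-year inequality values, weights, and the composite."""

    method: str
    values: pd.DataFrame        # province_id, year, one col per indicator, composite
    weights: np.ndarray         # entropy weight per indicator, sums to 1
    skipped: list               # (province_id, year) cells with < 2 cities

    def composite_series(self) -> pd.DataFrame:
        return self.values[["province_id", "year", "composite"]]


def compose_ehra(panel: pd.DataFrame, method: str = "theil") -> EquityIndexSet:
    """Composite equity index per province-year from a city resource panel.

    For each province-year, the chosen inequality measure of each of the four
    normalized indicators is computed across that province's cities; entropy
    weights are then fit on the pooled province-year matrix and applied to
    yield one composite per cell.  Province-years with fewer than two cities
    are reported in ``skipped`` (index undefined, row dropped).
    """
    method = method.lower()
    if method not in _MEASURES:
        raise ValueError(f"method must be one of {sorted(_MEASURES)}")
    measure = _MEASURES[method]
    table = normalize_indicators(panel)
    if table[list(INDICATORS)].isna().any().any():
        raise ValueError("indicator table has missing values: fill the panel first")

    rows, skipped = [], []
    for (prov, year), grp in table.groupby(["province_id", "year"], sort=True):
        if len(grp) < 2:
            skipped.append((prov, year))
            continue
        rows.append({"province_id": prov, "year": year,
                     **{c: measure(grp[c].to_numpy()) for c in INDICATORS}})
    if not rows:
        raise ValueError("no province-year with >= 2 cities")
    values = pd.DataFrame(rows)
    weights = entropy_weights(values[list(INDICATORS)].to_numpy())
    values["composite"] = values[list(INDICATORS)].to_numpy() @ weights
    return EquityIndexSet(method=method, values=values, weights=weights,
                          skipped=skipped)
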