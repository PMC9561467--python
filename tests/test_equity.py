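"""Equity indices: hand oracles, brute-force agreement, and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ehra
from ehra.equity import (INDICATORS, UndefinedIndexError, UnfillableSeriesError,
                         compose_ehra, cv, entropy_weights, fill_missing,
                         fill_panel, gini, normalize_indicators, theil)
from ehra.synthetic import (DGPConfig, gen_prefecture_resources,
                            inject_missingness)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def theil_oracle(y):
    y = np.asarray(y, float)
    ybar = y.mean()
    total = 0.0
    for yi in y:
        if yi > 0:
            total += (yi / ybar) * np.log(yi / ybar)
    return total / len(y)


def gini_oracle(y):
    y = np.asarray(y, float)
    n = len(y)
    return sum(abs(a - b) for a in y for b in y) / (2 * n * n * y.mean())


positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e3, allow_nan=False), min_size=2,
    max_size=30)


class TestScalarMeasures:
    def test_hand_oracles(self):
        # direct evaluation of the Theil formula with ybar = 2
        assert theil([1, 2, 3]) == pytest.approx(0.0872, abs=5e-5)
        # population SD 1, mean 2
        assert cv([1, 3]) == pytest.approx(0.5)
        # pairwise-difference formula
        assert gini([0, 1]) == pytest.approx(0.5)

    def test_agreement_with_bruteforce_on_random_vectors(self, rng):
        for _ in range(300):
            y = rng.gamma(2.0, 1.0, size=rng.integers(2, 40))
            assert theil(y) == pytest.approx(theil_oracle(y), abs=1e-12)
            assert gini(y) == pytest.approx(gini_oracle(y), abs=1e-12)
            assert cv(y) == pytest.approx(y.std() / y.mean(), abs=1e-12)

    @given(positive_vectors)
    @settings(max_examples=100, deadline=None)
    def test_invariances(self, values):
        """Nonnegativity, equality => 0, scale and permutation invariance."""
        y = np.asarray(values)
        for measure in (theil, cv, gini):
            v = measure(y)
            assert v >= -1e-12
            assert measure(3.7 * y) == pytest.approx(v, abs=1e-9, rel=1e-9)
            assert measure(y[::-1]) == pytest.approx(v, abs=1e-12)
        c = float(y[0])
        for measure in (theil, cv, gini):
            assert measure([c] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_gini_bounded_below_one(self, rng):
        for _ in range(50):
            y = rng.pareto(1.5, size=20) + 1e-6
            assert 0.0 <= gini(y) < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedIndexError):
            theil([0.0, 0.0])
        with pytest.raises(UndefinedIndexError):
            theil([1.0, -1.0])
        with pytest.raises(UndefinedIndexError):
            gini([])
        with pytest.raises(UndefinedIndexError):
            cv([0.0, 0.0])

    def test_zero_values_use_zero_log_zero_convention(self):
        # 0 * ln 0 = 0: finite answer with a zero entry
        assert np.isfinite(theil([0.0, 1.0, 2.0]))


class TestEntropyWeights:
    def test_identical_columns_get_equal_weights(self, rng):
        col = rng.gamma(2, 1, 20)
        w = entropy_weights(np.column_stack([col] * 4))
        assert w == pytest.approx([0.25] * 4, abs=1e-12)

    def test_constant_column_gets_zero_weight(self):
        x = np.array([[1.0, 5.0], [1.0, 2.0], [1.0, 9.0]])
        w = entropy_weights(x)
        assert w[0] == pytest.approx(0.0, abs=1e-9)
        assert w[1] == pytest.approx(1.0, abs=1e-9)
        # hand evaluation: column 2 shares (5/16, 2/16, 9/16)
        p = np.array([5, 2, 9]) / 16.0
        e2 = -(p * np.log(p)).sum() / np.log(3)
        assert e2 < 1.0  # informative column: entropy below the maximum

    def test_sum_one_nonnegative_permutation_invariant(self, rng):
        for _ in range(50):
            x = rng.gamma(2, 1, size=(15, 4))
            w = entropy_weights(x)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()
            perm = rng.permutation(15)
            assert entropy_weights(x[perm]) == pytest.approx(w, abs=1e-12)

    def test_all_constant_falls_back_to_equal_weights(self):
        w = entropy_weights(np.ones((5, 4)))
        assert w == pytest.approx([0.25] * 4)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            entropy_weights(np.ones((1, 4)))


class TestFillMissing:
    def test_interior_linear_interpolation(self):
        s = pd.Series([1.0, np.nan, 3.0], index=[2011, 2012, 2013])
        assert fill_missing(s).tolist() == [1.0, 2.0, 3.0]

    def test_leading_gap_geometric_backcast(self):
        # growth ratios (2, 2), geometric mean 2, backcast 2/2 = 1
        s = pd.Series([np.nan, 2.0, 4.0, 8.0], index=range(4))
        assert fill_missing(s).tolist() == [1.0, 2.0, 4.0, 8.0]

    def test_trailing_gap_geometric_forecast(self):
        s = pd.Series([2.0, 4.0, 8.0, np.nan], index=range(4))
        assert fill_missing(s).tolist() == [2.0, 4.0, 8.0, 16.0]

    def test_fully_observed_identity(self):
        s = pd.Series([3.0, 1.0, 4.0], index=range(3))
        pd.testing.assert_series_equal(fill_missing(s), s)

    def test_observed_values_never_touched(self, rng):
        vals = rng.gamma(5, 10, 10)
        s = pd.Series(vals, index=range(10))
        s.iloc[[2, 5, 9]] = np.nan
        out = fill_missing(s)
        obs = s.notna()
        assert (out[obs] == s[obs]).all()

    def test_too_few_observations_rejected(self):
        with pytest.raises(UnfillableSeriesError):
            fill_missing(pd.Series([np.nan, 1.0, np.nan]))

    def test_nonpositive_values_fall_back_to_carry(self, caplog):
        s = pd.Series([np.nan, 0.0, 4.0], index=range(3))
        out = fill_missing(s)
        assert out.iloc[0] == 0.0  # nearest-value carry

    def test_roundtrip_on_smooth_series(self):
        """Inject 5% missingness into linear-in-time counts; the fill rules
        recover the panel with small relative error."""
        pref = gen_prefecture_resources(
            DGPConfig(seed=6, n_provinces=4, n_years=8,
                      cities_per_province=(4, 6)), 0.15)
        # make each series linear in time so interpolation is near-exact
        for col in ("n_beds", "n_doctors"):
            base = pref.groupby(["province_id", "city_id"])[col].transform("first")
            step = pref["year"] - pref["year"].min()
            pref[col] = base * (1.0 + 0.05 * step)
        holed = inject_missingness(pref, 0.05, "internal", seed=9)
        filled = fill_panel(holed)
        merged = filled.merge(
            pref, on=["province_id", "city_id", "year"], suffixes=("_f", ""))
        for col in ("n_beds", "n_doctors"):
            rel = np.abs(merged[f"{col}_f"] - merged[col]) / merged[col]
            assert rel.max() < 0.05


class TestNormalizeAndCompose:
    def test_per_capita_and_per_area_scaling(self):
        panel = pd.DataFrame({
            "province_id": [1], "city_id": [1], "year": [2011],
            "n_institutions": [10], "n_beds": [100], "n_doctors": [50],
            "n_nurses": [60], "population": [50_000], "land_area": [100.0],
        })
        out = normalize_indicators(panel)
        assert out["beds_per_1000"].iloc[0] == pytest.approx(2.0)
        assert out["inst_per_km2"].iloc[0] == pytest.approx(0.1)

    def test_nonpositive_population_names_the_offending_key(self):
        panel = pd.DataFrame({
            "province_id": [7], "city_id": [3], "year": [2015],
            "n_institutions": [1], "n_beds": [1], "n_doctors": [1],
            "n_nurses": [1], "population": [0], "land_area": [10.0],
        })
        with pytest.raises(ValueError, match=r"province=7.*city=3.*year=2015"):
            normalize_indicators(panel)

    def test_composite_tracks_configured_dispersion(self):
        """Spearman correlation between the per-cell dispersion driver and
        the composite index exceeds 0.9 with many cities per province."""
        from scipy.stats import spearmanr
        cfg = DGPConfig(seed=8, n_provinces=8, n_years=4,
                        cities_per_province=(60, 80))
        rg = np.random.default_rng(42)
        driver = pd.DataFrame([
            {"province_id": i, "year": 2011 + t,
             "dispersion": rg.uniform(0.05, 0.6)}
            for i in range(1, 9) for t in range(4)])
        pref = gen_prefecture_resources(cfg, driver)
        res = compose_ehra(pref, "theil")
        merged = res.values.merge(driver, on=["province_id", "year"])
        rho = spearmanr(merged["dispersion"], merged["composite"]).statistic
        assert rho > 0.9

    def test_methods_rank_provinces_consistently(self):
        """Theil- and Gini-based composites order provinces the same way
        (rank correlation of province means > 0.8)."""
        from scipy.stats import spearmanr
        cfg = DGPConfig(seed=10, n_provinces=10, n_years=3,
                        cities_per_province=(20, 30))
        rg = np.random.default_rng(7)
        driver = pd.DataFrame([
            {"province_id": i, "year": 2011 + t,
             "dispersion": 0.05 + 0.06 * i + rg.uniform(0, 0.05)}
            for i in range(1, 11) for t in range(3)])
        pref = gen_prefecture_resources(cfg, driver)
        a = compose_ehra(pref, "theil").values.groupby("province_id")["composite"].mean()
        b = compose_ehra(pref, "gini").values.groupby("province_id")["composite"].mean()
        assert spearmanr(a, b).statistic > 0.8

    def test_single_city_province_reported_not_crashed(self):
        cfg = DGPConfig(seed=12, n_provinces=3, n_years=3,
                        cities_per_province=(4, 6))
        pref = gen_prefecture_resources(cfg, 0.2)
        pref = pref[~((pref["province_id"] == 2) & (pref["city_id"] > 1))]
        res = compose_ehra(pref, "theil")
        assert set(res.skipped) == {(2, 2011), (2, 2012), (2, 2013)}
        assert not ((res.values["province_id"] == 2)).any()
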