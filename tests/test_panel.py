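"""Panel estimators against the dummy-variable oracle, plus diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import lsdv_fit, make_two_way_panel
from ehra.panel import (ModelSpec, RankDeficientError, cluster_cov,
                        driscoll_kraay_cov, fit_2sls, fit_panel, hausman_test,
                        poolability_ftest, vif, within_transform)


class TestWithinTransform:
    def test_pure_fe_series_becomes_zero(self):
        n, t = 6, 5
        phi = np.arange(n)[:, None] * 1.7
        omega = np.arange(t)[None, :] * -0.9
        panel = pd.DataFrame({
            "province_id": np.repeat(np.arange(n), t),
            "year": np.tile(np.arange(t), n),
            "v": (phi + omega).ravel(),
        })
        out = within_transform(panel, ["v"], "unit+time")
        assert np.abs(out["v"]).max() < 1e-12

    def test_balanced_single_pass_within_means_vanish(self, rng):
        panel = make_two_way_panel(seed=1, n=8, t=6)
        out = within_transform(panel, ["y", "x"], "unit+time")
        for key in ("province_id", "year"):
            assert out.groupby(key)[["y", "x"]].mean().abs().max().max() < 1e-12

    def test_unbalanced_agrees_with_dummy_projection(self, rng):
        """Iterated demeaning equals projection on unit+time dummies."""
        panel = make_two_way_panel(seed=2, n=7, t=8)
        panel = panel.drop(index=rng.choice(len(panel), 9, replace=False))
        panel = panel.reset_index(drop=True)
        out = within_transform(panel, ["y"], "unit+time")
        # oracle: residual from regressing y on the full dummy set
        D = [np.ones(len(panel))]
        for u in np.sort(panel["province_id"].unique())[1:]:
            D.append((panel["province_id"] == u).to_numpy(float))
        for t_ in np.sort(panel["year"].unique())[1:]:
            D.append((panel["year"] == t_).to_numpy(float))
        Dm = np.column_stack(D)
        beta, _, _, _ = np.linalg.lstsq(Dm, panel["y"].to_numpy(), rcond=None)
        resid = panel["y"].to_numpy() - Dm @ beta
        assert np.abs(out["y"].to_numpy() - resid).max() < 1e-8

    def test_singleton_units_dropped_with_warning(self):
        panel = make_two_way_panel(seed=3, n=4, t=5)
        panel = pd.concat([panel, pd.DataFrame({
            "province_id": [99], "year": [2011], "y": [1.0], "x": [1.0]})],
            ignore_index=True)
        with pytest.warns(UserWarning, match="singleton"):
            out = within_transform(panel, ["y"], "unit+time")
        assert 99 not in out["province_id"].to_numpy()


class TestFixedEffects:
    def test_noise_free_dgp_exact_recovery(self):
        panel = make_two_way_panel(seed=4, sigma=0.0)
        fit = fit_panel(ModelSpec("y", "x", effects="unit+time"), panel, "fe")
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)

    def test_pooled_biased_when_x_correlates_with_effects(self):
        panel = make_two_way_panel(seed=5, corr_fe=2.0, sigma=0.2)
        fe = fit_panel(ModelSpec("y", "x", effects="unit+time"), panel, "fe")
        ols = fit_panel(ModelSpec("y", "x", effects="none"), panel, "pooled")
        assert abs(fe.params["x"] - 1.0) < 0.1
        assert abs(ols.params["x"] - 1.0) > 3 * abs(fe.params["x"] - 1.0)

    def test_hand_panel_matches_lsdv(self):
        """3 units x 3 periods: FE equals explicit dummy OLS to 1e-12."""
        panel = make_two_way_panel(seed=6, n=3, t=3)
        fit = fit_panel(ModelSpec("y", "x", effects="unit+time"), panel, "fe")
        oracle = lsdv_fit(panel, "y", ["x"])
        assert fit.params["x"] == pytest.approx(oracle["x"], abs=1e-12)

    def test_fe_matches_lsdv_on_random_panels(self, rng):
        """Balanced and unbalanced random panels, all effects modes."""
        for rep in range(12):
            n = int(rng.integers(4, 9))
            t = int(rng.integers(4, 9))
            panel = make_two_way_panel(seed=100 + rep, n=n, t=t, extra_cols=2)
            if rep % 2:  # unbalanced
                drop = rng.choice(len(panel), size=max(1, n * t // 10),
                                  replace=False)
                panel = panel.drop(index=drop).reset_index(drop=True)
            for effects in ("unit", "time", "unit+time"):
                spec = ModelSpec("y", "x", ("w0", "w1"), effects=effects)
                fit = fit_panel(spec, panel, "fe")
                oracle = lsdv_fit(panel, "y", ["x", "w0", "w1"], effects)
                for v in ("x", "w0", "w1"):
                    assert fit.params[v] == pytest.approx(oracle[v], abs=1e-10)

    def test_r2_monotone_in_regressors(self):
        panel = make_two_way_panel(seed=8, extra_cols=2)
        f1 = fit_panel(ModelSpec("y", "x", effects="none"), panel, "pooled")
        f2 = fit_panel(ModelSpec("y", "x", ("w0",), effects="none"), panel,
                       "pooled")
        assert 0.0 <= f1.r2_overall <= f2.r2_overall <= 1.0

    def test_rank_deficient_design_names_columns(self):
        panel = make_two_way_panel(seed=9)
        panel["x_dup"] = panel["x"]
        with pytest.raises(RankDeficientError, match="x"):
            fit_panel(ModelSpec("y", "x", ("x_dup",), effects="unit+time"),
                      panel, "fe")

    def test_covariance_matrices_symmetric_psd(self):
        panel = make_two_way_panel(seed=10, factor=1.0)
        for cov in ("classical", "robust_3way", "cluster"):
            fit = fit_panel(ModelSpec("y", "x", ("w0",), effects="unit+time",
                                      cov=cov),
                            make_two_way_panel(seed=10, extra_cols=1), "fe")
            V = fit.cov.to_numpy()
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() > -1e-14
            assert (fit.std_errors > 0).all()


class TestRobustCovariance:
    def test_iid_errors_robust_close_to_classical(self):
        """Sanity bound: under iid errors on a T = 40 panel the kernel SE
        stays within ~15% of the classical SE on average."""
        ratios = []
        for rep in range(120):
            panel = make_two_way_panel(seed=200 + rep, t=40)
            fc = fit_panel(ModelSpec("y", "x", effects="unit+time",
                                     cov="classical"), panel, "fe")
            fd = fit_panel(ModelSpec("y", "x", effects="unit+time",
                                     cov="robust_3way"), panel, "fe")
            ratios.append(fd.std_errors["x"] / fc.std_errors["x"])
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_common_shocks_break_classical_but_not_kernel(self):
        """Shared-loading factor errors: classical CIs undercover badly,
        kernel CIs (with t(T-1) quantiles) stay near nominal."""
        R = 200
        cov_c = cov_dk = 0
        for rep in range(R):
            panel = make_two_way_panel(seed=400 + rep, t=40, factor=2.0)
            fc = fit_panel(ModelSpec("y", "x", effects="unit+time",
                                     cov="classical"), panel, "fe")
            fd = fit_panel(ModelSpec("y", "x", effects="unit+time",
                                     cov="robust_3way"), panel, "fe")
            qc = stats.t.ppf(0.975, fc.df_resid)
            qd = stats.t.ppf(0.975, 39)
            cov_c += abs(fc.params["x"] - 1) <= qc * fc.std_errors["x"]
            cov_dk += abs(fd.params["x"] - 1) <= qd * fd.std_errors["x"]
        assert cov_c / R < 0.85
        assert 0.90 <= cov_dk / R <= 0.99

    def test_too_few_periods_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            driscoll_kraay_cov(X, np.ones(4), np.array([0, 0, 1, 1]), 2)


class TestHausman:
    def test_identical_fits_give_zero(self):
        panel = make_two_way_panel(seed=11)
        fe = fit_panel(ModelSpec("y", "x", effects="unit"), panel, "fe")
        H, df, p = hausman_test(fe, fe)
        assert H == 0.0 and p == 1.0

    def test_size_and_power(self):
        """Uncorrelated effects: rejection near alpha.  Effects correlated
        with the regressor: random effects inconsistent, test rejects."""
        R = 120
        spec = ModelSpec("y", "x", effects="unit", cov="classical")
        rej0 = rej1 = 0
        for rep in range(R):
            p0 = make_two_way_panel(seed=600 + rep, n=50)
            H, _, pv = hausman_test(fit_panel(spec, p0, "fe"),
                                    fit_panel(spec, p0, "re"))
            rej0 += pv < 0.05
            p1 = make_two_way_panel(seed=900 + rep, n=50, corr_fe=0.5)
            H, _, pv = hausman_test(fit_panel(spec, p1, "fe"),
                                    fit_panel(spec, p1, "re"))
            rej1 += pv < 0.05
        assert 0.005 < rej0 / R < 0.13
        assert rej1 / R > 0.8

    def test_disjoint_coefficients_rejected(self):
        panel = make_two_way_panel(seed=12, extra_cols=1)
        a = fit_panel(ModelSpec("y", "x", effects="unit"), panel, "fe")
        b = fit_panel(ModelSpec("y", "w0", effects="unit"), panel, "fe")
        with pytest.raises(ValueError):
            hausman_test(a, b)


class TestPoolability:
    def test_large_unit_effects_detected(self):
        panel = make_two_way_panel(seed=13, phi_sd=3.0)
        F, df1, df2, p = poolability_ftest(
            panel, ModelSpec("y", "x", effects="unit"))
        assert F > stats.f.ppf(0.99, df1, df2)
        assert p < 0.01

    def test_no_effects_size_near_alpha(self):
        R, rej = 100, 0
        for rep in range(R):
            # no unit or time effects: the pooled null holds exactly
            panel = make_two_way_panel(seed=1200 + rep, phi_sd=0.0,
                                       omega_sd=0.0)
            _, _, _, p = poolability_ftest(
                panel, ModelSpec("y", "x", effects="unit"))
            rej += p < 0.05
        assert 0.005 < rej / R < 0.13

    def test_single_unit_rejected(self):
        panel = make_two_way_panel(seed=14, n=1, t=8)
        with pytest.raises(ValueError):
            poolability_ftest(panel, ModelSpec("y", "x", effects="unit"))


class TestVif:
    def test_orthogonal_columns_give_one(self):
        # zero-mean mutually orthogonal contrast columns
        a = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        b = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        X = pd.DataFrame({"a": a, "b": b, "c": a * b})
        assert vif(X).max() == pytest.approx(1.0, abs=1e-10)

    def test_known_correlation_closed_form(self, rng):
        """corr = 0.9 exactly => VIF = 1/(1-0.81) = 5.263."""
        z = rng.standard_normal(4000)
        e = rng.standard_normal(4000)
        a = z
        b = 0.9 * z + np.sqrt(1 - 0.81) * e
        # orthogonalize exactly to correlation 0.9
        b = 0.9 * (a / a.std()) + np.sqrt(1 - 0.81) * \
            ((e - e.mean()) / e.std())
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        r = np.corrcoef(a, b)[0, 1]
        v = vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1.0 / (1.0 - r**2), rel=1e-6)

    def test_duplicated_column_flagged_unbounded(self, rng):
        x = rng.standard_normal(50)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v).all()


class TestTwoSLS:
    def test_self_instrument_reproduces_ols(self):
        panel = make_two_way_panel(seed=15, extra_cols=1)
        panel["z"] = panel["x"]
        spec = ModelSpec("y", "x", ("w0",), effects="unit+time")
        iv = fit_2sls(spec, panel, instrument="z")
        fe = fit_panel(spec, panel, "fe")
        assert iv.params["x"] == pytest.approx(fe.params["x"], abs=1e-10)

    def test_lag_instrument_drops_one_period(self):
        panel = make_two_way_panel(seed=16, n=22, t=10)
        iv = fit_2sls(ModelSpec("y", "x", effects="unit+time"), panel)
        assert iv.nobs == 22 * 9  # 198 for the emulated study dimensions
        assert iv.diagnostics["first_stage"]["F"] > 10

    def test_bias_reduction_under_endogeneity(self):
        """corr(x innovations, errors) = 0.5: the lagged instrument removes
        most of the OLS bias (>= 3x reduction) on a T = 40 panel."""
        b_ols, b_iv = [], []
        spec = ModelSpec("y", "x", effects="unit+time")
        for rep in range(120):
            panel = make_two_way_panel(seed=1500 + rep, t=40, endog=0.5)
            b_ols.append(fit_panel(spec, panel, "fe").params["x"])
            b_iv.append(fit_2sls(spec, panel).params["x"])
        bias_ols = abs(np.mean(b_ols) - 1.0)
        bias_iv = abs(np.mean(b_iv) - 1.0)
        assert bias_iv < bias_ols / 3.0

    def test_weak_instrument_warns_not_fails(self, rng):
        panel = make_two_way_panel(seed=17, n=10, t=6)
        panel["z"] = rng.standard_normal(len(panel))  # irrelevant instrument
        with pytest.warns(UserWarning, match="weak instrument"):
            fit = fit_2sls(ModelSpec("y", "x", effects="unit+time"), panel,
                           instrument="z")
        assert np.isfinite(fit.params["x"])
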