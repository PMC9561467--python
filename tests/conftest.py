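import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_two_way_panel(
    seed: int,
    n: int = 22,
    t: int = 10,
    beta: float = 1.0,
    rho_x: float = 0.8,
    endog: float = 0.0,
    factor: float = 0.0,
    corr_fe: float = 0.0,
    phi_sd: float = 1.0,
    omega_sd: float = 1.0,
    sigma: float = 1.0,
    extra_cols: int = 0,
) -> pd.DataFrame:
    """Hand-rolled two-way FE data generator used as an independent DGP for
    estimator tests (kept separate from the package's synthetic module on
    purpose, so estimator checks do not share code with the object under
    test).

    ``endog`` correlates the error with x's innovations (its one-period lag
    stays a valid instrument up to O(1/T) demeaning terms); ``factor`` adds a
    shared-loading common shock to x and the error (cross-sectional
    dependence that classical covariances ignore); ``corr_fe`` correlates
    unit effects with the regressor level (random-effects inconsistency).
    """
    rg = np.random.default_rng(seed)
    u = rg.standard_normal((n, t))
    x = np.zeros((n, t))
    x[:, 0] = u[:, 0]
    for k in range(1, t):
        x[:, k] = rho_x * x[:, k - 1] + u[:, k]
    eps = rg.standard_normal((n, t))
    if endog:
        eps = endog * u + np.sqrt(1 - endog**2) * eps
    if factor:
        lam = rg.standard_normal(n)[:, None]
        x = x + lam * rg.standard_normal(t)[None, :]
        eps = eps + factor * lam * rg.standard_normal(t)[None, :]
    phi = phi_sd * rg.standard_normal(n)[:, None]
    if corr_fe:
        phi = phi + corr_fe * x.mean(axis=1, keepdims=True)
    omega = omega_sd * rg.standard_normal(t)[None, :]
    y = beta * x + phi + omega + sigma * eps
    out = pd.DataFrame({
        "province_id": np.repeat(np.arange(1, n + 1), t),
        "year": np.tile(np.arange(2011, 2011 + t), n),
        "y": y.ravel(),
        "x": x.ravel(),
    })
    for j in range(extra_cols):
        out[f"w{j}"] = rg.standard_normal(len(out))
    return out


def lsdv_fit(panel: pd.DataFrame, dependent: str, regressors: list[str],
             effects: str = "unit+time",
             unit_col: str = "province_id", time_col: str = "year"):
    """Dummy-variable OLS oracle: explicit unit/time dummies, lstsq solve."""
    X = [panel[r].to_numpy(float) for r in regressors]
    names = list(regressors)
    X.append(np.ones(len(panel)))
    names.append("const")
    if effects in ("unit", "unit+time"):
        for u in np.sort(panel[unit_col].unique())[1:]:
            X.append((panel[unit_col] == u).to_numpy(float))
            names.append(f"u{u}")
    if effects in ("time", "unit+time"):
        for t_ in np.sort(panel[time_col].unique())[1:]:
            X.append((panel[time_col] == t_).to_numpy(float))
            names.append(f"t{t_}")
    Xm = np.column_stack(X)
    beta, _, _, _ = np.linalg.lstsq(Xm, panel[dependent].to_numpy(float),
                                    rcond=None)
    return dict(zip(names, beta))
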