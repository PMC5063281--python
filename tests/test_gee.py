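"""GEE engine: closed-form checks, moment estimators, oracle equivalence."""

import numpy as np
import pytest

from dmdwalk import ExchangeableGEE, estimate_rho_phi
from dmdwalk.errors import DegreesOfFreedomError, SingularDesignError
from dmdwalk.gee import Z_975


def random_clustered(rng, n_clusters=25, max_size=6, p=4, rho=0.4, sigma=5.0):
    X_rows, y_rows, groups = [], [], []
    beta = rng.normal(0, 2, size=p)
    for g in range(n_clusters):
        n = rng.integers(1, max_size + 1)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        shared = rng.normal(0, sigma * np.sqrt(rho))
        eps = rng.normal(0, sigma * np.sqrt(1 - rho), size=n)
        y_rows.append(X @ beta + shared + eps)
        X_rows.append(X)
        groups += [g] * n
    return np.vstack(X_rows), np.concatenate(y_rows), np.array(groups)


def test_singleton_clusters_equal_ols(rng):
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    y = rng.normal(size=40)
    groups = np.arange(40)
    res = ExchangeableGEE(y, X, groups).fit()
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(res.params.to_numpy(), ols, rtol=0, atol=1e-10)
    assert res.rho == 0.0


def test_noiseless_exact(rng):
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    y = X @ beta
    groups = np.repeat(np.arange(10), 3)
    res = ExchangeableGEE(y, X, groups).fit()
    np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
    assert res.phi == pytest.approx(0.0, abs=1e-18)
    assert res.converged and res.iterations <= 2
    # zero residuals -> zero sandwich
    np.testing.assert_allclose(res.cov_robust.to_numpy(), 0.0, atol=1e-16)


def test_rho_phi_hand_example():
    # two clusters of size 2 with perfectly shared residuals
    residuals = np.array([1.0, 1.0, -1.0, -1.0])
    clusters = np.array(["a", "a", "b", "b"])
    rho, phi = estimate_rho_phi(residuals, clusters, p=0)
    assert phi == pytest.approx(1.0)
    assert rho == pytest.approx(0.99)  # true moment value 1.0, clamped


def test_rho_singletons_and_null(rng):
    rho, _ = estimate_rho_phi(rng.normal(size=30), np.arange(30), p=0)
    assert rho == 0.0
    resid = rng.normal(size=800)
    rho, phi = estimate_rho_phi(resid, np.repeat(np.arange(200), 4), p=0)
    assert abs(rho) <= 0.05
    assert phi == pytest.approx(1.0, abs=0.15)


def test_dof_error():
    with pytest.raises(DegreesOfFreedomError):
        estimate_rho_phi(np.ones(3), np.arange(3), p=5)


def test_singular_design(rng):
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    X = np.column_stack([X, X[:, 1] * 2.0])  # exact collinearity
    with pytest.raises(SingularDesignError):
        ExchangeableGEE(rng.normal(size=20), X, np.repeat(np.arange(10), 2)).fit()


def test_statsmodels_oracle_equivalence(rng):
    """beta, rho and robust SEs match the reference GEE implementation."""
    sm = pytest.importorskip("statsmodels.api")
    for _ in range(12):
        X, y, groups = random_clustered(rng)
        ours = ExchangeableGEE(y, X, groups).fit(tol=1e-12, maxiter=300)
        ref = sm.GEE(y, X, groups=groups, cov_struct=sm.cov_struct.Exchangeable()).fit(
            maxiter=300, ctol=1e-12
        )
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params, rtol=1e-5)
        np.testing.assert_allclose(ours.rho, ref.model.cov_struct.dep_params, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, rtol=1e-5)
        np.testing.assert_allclose(ours.phi, ref.scale, rtol=1e-5)


def test_scale_equivariance(rng):
    X, y, groups = random_clustered(rng)
    a = ExchangeableGEE(y, X, groups).fit()
    b = ExchangeableGEE(3.0 * y, X, groups).fit()
    np.testing.assert_allclose(b.params.to_numpy(), 3.0 * a.params.to_numpy(), rtol=1e-7)
    assert b.rho == pytest.approx(a.rho, abs=1e-7)
    assert b.phi == pytest.approx(9.0 * a.phi, rel=1e-7)


def test_estimating_equation_residual(rng):
    X, y, groups = random_clustered(rng)
    res = ExchangeableGEE(y, X, groups).fit()
    assert res._state["score_norm"] < 1e-6 * np.abs(y).max()


def test_forced_rho_zero_is_ols(rng):
    # singleton clusters force rho = 0; GEE then reproduces OLS exactly
    X, y, _ = random_clustered(rng)
    res = ExchangeableGEE(y, X, np.arange(len(y))).fit()
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(res.params.to_numpy(), ols, atol=1e-9)


def test_sandwich_approaches_ols_covariance(rng):
    """With independent homoskedastic data the sandwich converges to the
    naive OLS covariance."""
    n = 2000
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
    res = ExchangeableGEE(y, X, np.arange(n)).fit()
    r = y - X @ res.params.to_numpy()
    s2 = r @ r / (n - 3)
    ols_cov = s2 * np.linalg.inv(X.T @ X)
    ratio = np.diag(res.cov_robust.to_numpy()) / np.diag(ols_cov)
    assert np.all((0.8 < ratio) & (ratio < 1.2))


def test_sandwich_function_matches_fit(rng):
    from dmdwalk.design import DesignMatrix
    from dmdwalk.gee import sandwich_covariance

    X, y, groups = random_clustered(rng)
    res = ExchangeableGEE(y, X, groups).fit()
    design = DesignMatrix(
        row_keys=[str(i) for i in range(len(y))],
        cluster_ids=groups.astype(object),
        column_names=res.params.index.to_list(),
        values=X,
        outcome=y,
    )
    cov = sandwich_covariance(design, res.params.to_numpy(), res.rho, res.phi)
    np.testing.assert_allclose(cov, res.cov_robust.to_numpy(), rtol=1e-10)


def test_predict_and_permutation(rng):
    X, y, groups = random_clustered(rng)
    res = ExchangeableGEE(y, X, groups).fit()
    preds = res.predict(X)
    perm = rng.permutation(len(y))
    np.testing.assert_array_equal(res.predict(X[perm]), preds[perm])


def test_intercept_only_prediction_is_gls_mean(rng):
    X, y, groups = random_clustered(rng, p=1)
    res = ExchangeableGEE(y, X, groups).fit()
    # closed form: GLS mean with exchangeable weights 1/(1 - rho + n_i rho)
    rho = res.rho
    weights = []
    for g in np.unique(groups):
        n = (groups == g).sum()
        weights.extend([1.0 / (1.0 - rho + n * rho)] * n)
    w = np.array(weights)
    gls_mean = (w * y).sum() / w.sum()
    assert res.params.iloc[0] == pytest.approx(gls_mean, rel=1e-6)
    np.testing.assert_allclose(res.predict(), gls_mean)


def test_coefficient_table_quantiles():
    class Fake:
        pass

    # manufactured fit: estimate 0 with SE 1, and the 95% boundary case
    X = np.ones((4, 1))
    model = ExchangeableGEE(np.zeros(4), X, np.arange(4), ["c"])
    res = model.fit()
    res.params.iloc[0] = 0.0
    res.cov_robust.iloc[0, 0] = 1.0
    table = res.coefficient_table()
    assert table.loc["c", "ci_lower"] == pytest.approx(-Z_975)
    assert table.loc["c", "p_value"] == pytest.approx(1.0, abs=1e-3)
    res.params.iloc[0] = Z_975
    assert res.pvalues.iloc[0] == pytest.approx(0.05, abs=5e-4)


def test_type_i_error_of_null_coefficient(rng):
    """A covariate with zero true effect is flagged at ~ the nominal 5% rate."""
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        groups = np.repeat(np.arange(40), 3)
        shared = rng.normal(0, 1, size=40)[groups]
        y = 2.0 + 1.5 * X[:, 1] + 0.0 * X[:, 2] + shared + rng.normal(size=n)
        res = ExchangeableGEE(y, X, groups).fit()
        z = res.params.iloc[2] / res.bse.iloc[2]
        hits += abs(z) > 1.96
    assert 0.02 <= hits / n_rep <= 0.12  # robust-SE small-sample inflation allowed
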