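"""Coordinate-descent solver: closed forms, oracles, KKT and path laws."""

import numpy as np
import pytest

from conftest import enet_objective, fista_enet
from gwaselect.solver import (
    SolverConfig,
    fit_path,
    lambda_path,
    objective,
    predict,
    soft_threshold,
)

TIGHT = SolverConfig(tol=1e-14)


def _standardized(rng, n, p):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    return X


def test_soft_threshold_definition():
    assert soft_threshold(3.0, 1.0) == pytest.approx(2.0)
    assert soft_threshold(-0.5, 1.0) == 0.0
    assert soft_threshold(-3.0, 1.0) == pytest.approx(-2.0)
    for z in (-2.5, 0.0, 1.7):
        assert soft_threshold(z, 0.0) == pytest.approx(z)
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


def test_lambda_max_single_predictor():
    # one standardized predictor with <x, y>/n = 0.8 forces lambda_max = 0.8
    n = 250
    x = np.tile([1.0, -1.0], n // 2)
    y = 0.8 * x
    lam = lambda_path(x[:, None], y, alpha=1.0)
    assert lam[0] == pytest.approx(0.8, rel=1e-12)


def test_lambda_grid_geometry_and_alpha_scaling(rng):
    X = rng.normal(size=(60, 15))
    y = rng.normal(size=60)
    cfg = SolverConfig(epsilon=0.001, K=100)
    lam = lambda_path(X, y, 1.0, cfg)
    assert len(lam) == 100
    assert lam[-1] / lam[0] == pytest.approx(0.001)
    ratios = lam[1:] / lam[:-1]
    assert np.allclose(ratios, ratios[0])
    lam01 = lambda_path(X, y, 0.1, cfg)
    assert lam01[0] == pytest.approx(10 * lam[0])


@pytest.mark.parametrize("alpha", [1.0, 0.3])
def test_all_zero_at_lambda_max_with_kkt(rng, alpha):
    X = rng.normal(size=(50, 12))
    y = rng.normal(size=50)
    fit = fit_path(X, y, alpha, config=TIGHT)
    assert np.all(fit.coefs[:, 0] == 0.0)
    # KKT at lambda_max: |<x_j, y_c>|/n <= lambda * alpha for every j
    Xs = (X - X.mean(0)) / X.std(0)
    g = np.abs(Xs.T @ (y - y.mean())) / len(y)
    assert np.all(g <= fit.lambda_seq[0] * alpha + 1e-10)


def test_orthonormal_design_soft_threshold_closed_form(rng):
    """With X'X/n = I and alpha=1, beta_j(lam) = S(beta_ols_j, lam) exactly."""
    n, p = 64, 8
    M = rng.normal(size=(n, p))
    Q, _ = np.linalg.qr(M - M.mean(0))
    X = Q * np.sqrt(n)  # columns orthonormal under the 1/n inner product
    y = rng.normal(size=n) + X[:, 0] - 0.5 * X[:, 3]
    yc = y - y.mean()
    b_ols = X.T @ yc / n
    lam_seq = np.geomspace(np.abs(b_ols).max(), 0.01, 30)
    fit = fit_path(X, y, 1.0, lam_seq, config=TIGHT)
    for k, lam in enumerate(lam_seq):
        expect = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        got = fit.coefs[:, k] * X.std(0)
        assert np.allclose(got, expect, atol=1e-8)


def test_small_lambda_recovers_ols(rng):
    n, p = 50, 8
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
    lam = lambda_path(X, y, 1.0, SolverConfig(epsilon=1e-7, K=60, tol=1e-15))
    fit = fit_path(X, y, 1.0, lam, config=SolverConfig(epsilon=1e-7, K=60, tol=1e-15))
    Z = np.hstack([np.ones((n, 1)), X])
    ols = np.linalg.lstsq(Z, y, rcond=None)[0]
    assert np.allclose(fit.coefs[:, -1], ols[1:], atol=1e-6)
    assert fit.intercepts[-1] == pytest.approx(ols[0], abs=1e-6)
    # predictions at the smallest lambda equal OLS fitted values
    pred = predict(fit, X, len(lam) - 1)
    assert np.allclose(pred, Z @ ols, atol=1e-5)


@pytest.mark.parametrize("alpha", [1.0, 0.6, 0.2])
def test_matches_proximal_gradient_oracle(rng, alpha):
    """CCD solutions minimize the elastic-net objective (FISTA cross-check)."""
    n, p = 40, 10
    X = _standardized(rng, n, p)
    y = X[:, 0] * 1.2 - X[:, 4] + rng.normal(size=n)
    yc = y - y.mean()
    lam_seq = lambda_path(X, y, alpha, SolverConfig(K=5, epsilon=0.05))
    fit = fit_path(X, y, alpha, lam_seq, config=TIGHT)
    for k, lam in enumerate(lam_seq):
        b_oracle = fista_enet(X, yc, lam, alpha)
        f_ours = enet_objective(X, yc, fit.coefs[:, k] * X.std(0), lam, alpha)
        f_oracle = enet_objective(X, yc, b_oracle, lam, alpha)
        assert f_ours <= f_oracle * (1 + 1e-6) + 1e-12
        # KKT stationarity at the reported solution
        b = fit.coefs[:, k] * X.std(0)
        g = X.T @ (yc - X @ b) / n - lam * (1 - alpha) * b
        on = b != 0
        assert np.all(np.abs(g[~on]) <= lam * alpha + 1e-4)
        assert np.allclose(g[on], lam * alpha * np.sign(b[on]), atol=1e-4)


def test_alpha_zero_matches_analytic_ridge(rng):
    n, p = 60, 6
    X = _standardized(rng, n, p)
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    yc = y - y.mean()
    lam = 0.7
    fit = fit_path(X, y, 0.0, np.array([2.0, lam]), config=TIGHT)
    # (X'X/n + lam I) beta = X'y/n
    b_ridge = np.linalg.solve(X.T @ X / n + lam * np.eye(p), X.T @ yc / n)
    assert np.allclose(fit.coefs[:, 1] * X.std(0), b_ridge, atol=1e-8)


def test_sparsity_nondecreasing_in_alpha(rng):
    n, p = 80, 30
    X = rng.normal(size=(n, p))
    y = X[:, :4] @ np.array([2.0, -1.5, 1.0, 0.5]) + rng.normal(size=n)
    lam = 0.25
    nz_prev = p + 1
    for alpha in (0.05, 0.3, 0.6, 1.0):
        fit = fit_path(X, y, alpha, np.array([10.0, lam]), config=TIGHT)
        nz = int((fit.coefs[:, 1] != 0).sum())
        assert nz <= nz_prev
        nz_prev = nz


def test_objective_nonincreasing_along_sweeps(rng):
    n, p = 50, 20
    X = rng.normal(size=(n, p))
    y = X[:, 0] - X[:, 5] + rng.normal(size=n)
    lam_seq = lambda_path(X, y, 0.5)
    fit = fit_path(X, y, 0.5, lam_seq)
    vals = [
        objective(X, y, fit.intercepts[k], fit.coefs[:, k], 0.5, lam_seq[k])
        for k in range(fit.K)
    ]
    # warm-started path: each solution optimal at its own lambda, so the
    # objective evaluated at the *same* lambda for neighbours must not beat it
    for k in range(1, fit.K):
        f_prev_here = objective(X, y, fit.intercepts[k - 1], fit.coefs[:, k - 1], 0.5, lam_seq[k])
        assert vals[k] <= f_prev_here + 1e-10


def test_unpenalized_covariates_stay_at_ols(rng):
    n, p = 70, 12
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + rng.normal(size=n)
    pf = np.ones(p)
    pf[:2] = 0.0  # first two columns are fixed covariates
    fit = fit_path(X, y, 1.0, penalty_factors=pf, config=TIGHT)
    assert np.all(fit.coefs[2:, 0] == 0.0)
    Z = np.hstack([np.ones((n, 1)), X[:, :2]])
    ols = np.linalg.lstsq(Z, y, rcond=None)[0]
    assert np.allclose(fit.coefs[:2, 0], ols[1:], atol=1e-8)


def test_zero_variance_column_skipped(rng):
    X = rng.normal(size=(40, 5))
    X[:, 2] = 3.0
    y = X[:, 0] + rng.normal(size=40)
    fit = fit_path(X, y, 1.0)
    assert np.all(fit.coefs[2] == 0.0)


def test_predict_shapes_and_arithmetic():
    from gwaselect.solver import PathFit

    fit = PathFit(
        alpha=1.0,
        lambda_seq=np.array([1.0]),
        intercepts=np.array([1.0]),
        coefs=np.array([[2.0]]),
        penalty_factors=np.ones(1),
        standardize=True,
        n_iter=np.array([1]),
        converged=np.array([True]),
    )
    assert predict(fit, np.array([[3.0]]), 0)[0] == pytest.approx(7.0)
    zero = PathFit(
        alpha=1.0,
        lambda_seq=np.array([1.0]),
        intercepts=np.array([0.5]),
        coefs=np.zeros((4, 1)),
        penalty_factors=np.ones(4),
        standardize=True,
        n_iter=np.array([1]),
        converged=np.array([True]),
    )
    assert np.allclose(predict(zero, np.ones((3, 4)), 0), 0.5)
    with pytest.raises(IndexError):
        predict(zero, np.ones((3, 4)), 5)


def test_input_validation(rng):
    X = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    with pytest.raises(ValueError):
        fit_path(X, y, 1.5)
    with pytest.raises(ValueError):
        lambda_path(X, y, 1.0, penalty_factors=np.zeros(4))
    with pytest.raises(ValueError):
        fit_path(X, np.append(y[:-1], np.inf), 1.0)
    with pytest.raises(ValueError):
        fit_path(X, y, 1.0, lambda_seq=np.array([0.1, 0.5]))  # increasing
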