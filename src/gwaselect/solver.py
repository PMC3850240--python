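"""Elastic-net / lasso / ridge penalized least squares on a lambda path.

The estimator minimizes, for penalty weight ``alpha`` in [0, 1] and
per-variable penalty factors ``pf_j >= 0``,

    (1 / 2n) * sum_i (y_i - beta0 - x_i' beta)^2
        + lambda * sum_j pf_j * (alpha * |beta_j| + (1 - alpha)/2 * beta_j^2)

by cyclic coordinate descent: at each step the simple least-squares
coefficient on the partial residual is soft-thresholded for the l1 part
and proportionally shrunk for the l2 part.  ``alpha=1`` is the lasso,
``alpha=0`` ridge regression.  The path runs from ``lambda_max`` (smallest
lambda with all penalized coefficients zero) down to
``epsilon * lambda_max`` on a log-spaced grid, warm-starting each fit from
the previous one.

Predictors are standardized to zero mean and unit (1/n) variance
internally and coefficients are returned on the original scale; the
intercept is never penalized.  A penalty factor of 0 keeps a covariate
permanently in the model (used for population-structure eigenvectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._ccd import ccd_path
from .containers import GenotypeMatrix

__all__ = [
    "SolverConfig",
    "PathFit",
    "soft_threshold",
    "lambda_path",
    "fit_path",
    "predict",
]


@dataclass
class SolverConfig:
    """Path and convergence settings.

    epsilon : ratio lambda_min / lambda_max (default 0.001)
    K : number of lambda values on the log-spaced path (default 100)
    tol : relative convergence tolerance: a sweep converges when
        max_j (delta beta_j)^2 < tol * Var(y), with beta on the
        standardized scale (default 1e-7, the convention of
        coordinate-descent GLM software)
    max_iter : cap on coordinate sweeps per lambda
    """

    epsilon: float = 0.001
    K: int = 100
    tol: float = 1e-7
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class PathFit:
    """Coefficients along a decreasing lambda path at fixed alpha.

    ``coefs`` has shape (p, K) on the original predictor scale;
    ``intercepts`` has length K.  ``penalty_factors`` records which columns
    were penalized (0 = unpenalized covariate).
    """

    alpha: float
    lambda_seq: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray
    penalty_factors: np.ndarray
    standardize: bool
    n_iter: np.ndarray
    converged: np.ndarray

    @property
    def K(self) -> int:
        return len(self.lambda_seq)

    @property
    def p(self) -> int:
        return self.coefs.shape[0]

    def nonzero(self, lambda_index: int, penalized_only: bool = True) -> np.ndarray:
        """0-based indices of nonzero coefficients at one lambda."""
        nz = np.flatnonzero(self.coefs[:, lambda_index] != 0.0)
        if penalized_only:
            nz = nz[self.penalty_factors[nz] > 0]
        return nz


def soft_threshold(z: float, gamma: float):
    """sign(z) * max(|z| - gamma, 0); gamma must be nonnegative."""
    if np.any(np.asarray(gamma) < 0):
        raise ValueError("threshold gamma must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def _as_float_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("design contains non-finite values")
    return X


def _standardize(X: np.ndarray):
    """Column means, 1/n standard deviations, and the standardized p x n
    transpose (zero-variance columns flagged and left as zeros)."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/n convention
    ok = sd > 0
    XT = np.empty((X.shape[1], n), dtype=np.float64)
    np.copyto(XT, X.T)
    XT -= mean[:, None]
    XT[ok] /= sd[ok, None]
    XT[~ok] = 0.0
    return mean, sd, ok, np.ascontiguousarray(XT)


def _prep(X, y, penalty_factors):
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("response length does not match design rows")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    p = X.shape[1]
    if penalty_factors is None:
        pf = np.ones(p)
    else:
        pf = np.asarray(penalty_factors, dtype=np.float64).ravel()
        if len(pf) != p or (pf < 0).any():
            raise ValueError("penalty_factors must be length-p nonnegative")
    if not (pf > 0).any():
        raise ValueError("all penalty factors are zero: the path is undefined")
    return X, y, pf


def _covariate_residual(XT, yc, pf, ok):
    """Residual of the centered response after OLS on the unpenalized
    covariates (equals the centered response when there are none)."""
    free = np.flatnonzero((pf == 0.0) & ok)
    if len(free) == 0:
        return yc
    A = XT[free].T
    coef, *_ = np.linalg.lstsq(A, yc, rcond=None)
    return yc - A @ coef


def lambda_path(X, y, alpha: float, config: SolverConfig | None = None,
                penalty_factors=None) -> np.ndarray:
    """Log-spaced lambda sequence from lambda_max down to epsilon*lambda_max.

    lambda_max is the smallest lambda at which every penalized coefficient
    is zero: max over penalized j of |<x_j, r>| / (n * alpha * pf_j), with
    x_j standardized and r the centered response (residualized on any
    unpenalized covariates so the all-zero point is exact).  For
    ``alpha=0`` (ridge) no such finite point exists; alpha is clamped to
    0.001 for path construction only.
    """
    config = config or SolverConfig()
    X, y, pf = _prep(X, y, penalty_factors)
    n = X.shape[0]
    _, _, ok, XT = _standardize(X)
    yc = y - y.mean()
    r = _covariate_residual(XT, yc, pf, ok)
    a = max(float(alpha), 0.001)
    pen = np.flatnonzero((pf > 0) & ok)
    grad = np.abs(XT[pen] @ r) / (n * a * pf[pen])
    lam_max = float(grad.max())
    if lam_max <= 0:
        lam_max = 1e-3  # response orthogonal to every predictor
    return np.geomspace(lam_max, lam_max * config.epsilon, config.K)


def fit_path(X, y, alpha: float, lambda_seq=None, penalty_factors=None,
             config: SolverConfig | None = None) -> PathFit:
    """Fit the elastic-net coefficient path by coordinate descent."""
    config = config or SolverConfig()
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lambda_seq is None:
        lambda_seq = lambda_path(X, y, alpha, config, penalty_factors)
    lambda_seq = np.asarray(lambda_seq, dtype=np.float64).ravel()
    if len(lambda_seq) > 1 and not (np.diff(lambda_seq) < 0).all():
        raise ValueError("lambda_seq must be strictly decreasing")
    X, y, pf = _prep(X, y, penalty_factors)
    n = X.shape[0]
    mean, sd, ok, XT = _standardize(X)
    ybar = y.mean()
    yc = y - ybar

    pf_k = pf.copy()
    pf_k[~ok] = np.inf  # zero-variance columns can never activate
    betas_std, n_iter, converged = ccd_path(
        XT, yc, lambda_seq, float(alpha), pf_k, float(config.tol), int(config.max_iter)
    )

    coefs = np.zeros((X.shape[1], len(lambda_seq)))
    coefs[ok] = (betas_std[:, ok] / sd[ok]).T
    intercepts = ybar - mean @ coefs
    return PathFit(
        alpha=float(alpha),
        lambda_seq=lambda_seq,
        intercepts=intercepts,
        coefs=coefs,
        penalty_factors=pf,
        standardize=True,
        n_iter=n_iter,
        converged=converged,
    )


def predict(fit: PathFit, X_new, lambda_index: int) -> np.ndarray:
    """Fitted values beta0 + X beta at one lambda of the path."""
    X_new = _as_float_matrix(X_new)
    if X_new.shape[1] != fit.p:
        raise ValueError("X_new column count does not match the fit")
    if not -fit.K <= lambda_index < fit.K:
        raise IndexError("lambda_index out of range")
    return fit.intercepts[lambda_index] + X_new @ fit.coefs[:, lambda_index]


def objective(X, y, beta0: float, beta, alpha: float, lam: float,
              penalty_factors=None) -> float:
    """Value of the penalized least-squares objective (1/2n scaling).

    Exposed for diagnostics and testing; ``beta`` is on the original
    predictor scale, so the penalty is evaluated on the standardized
    coefficients beta_j * sd_j to match what the solver minimizes.
    """
    X, y, pf = _prep(X, y, penalty_factors)
    n = X.shape[0]
    beta = np.asarray(beta, dtype=float).ravel()
    sd = X.std(axis=0)
    b_std = beta * sd
    resid = y - beta0 - X @ beta
    loss = 0.5 * np.dot(resid, resid) / n
    pen = lam * np.sum(pf * (alpha * np.abs(b_std) + 0.5 * (1 - alpha) * b_std**2))
    return float(loss + pen)
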