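"""k-fold cross-validation over the lambda path and selection rules.

Implements the two standard tuning rules for penalized regression:

``min``
    the lambda minimizing the cross-validated mean squared error (minMSE);
``1se``
    the largest lambda whose CV MSE is within one standard error of that
    minimum (minMSE + 1SE), the more conservative rule that trades a
    slightly worse fit for a sparser model.

The lambda grid is computed once on the full data and shared across folds;
the per-lambda standard error is the SD of the k fold-level MSEs divided
by sqrt(k).  ``repeated_cv_lambda`` averages the chosen lambda over
several independent CV runs, the stabilization used when fold noise moves
the selected lambda between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix
from .solver import PathFit, SolverConfig, fit_path, lambda_path

__all__ = [
    "CVResult",
    "SelectionResult",
    "make_folds",
    "cv_path",
    "select_variables",
    "repeated_cv_lambda",
]


@dataclass
class CVResult:
    """Cross-validated error curve along the lambda path."""

    lambda_seq: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray
    fold_ids: np.ndarray
    seed: int

    @property
    def index_min(self) -> int:
        return int(np.argmin(self.mean_mse))

    @property
    def lambda_min(self) -> float:
        """Lambda achieving the minimum CV MSE."""
        return float(self.lambda_seq[self.index_min])

    @property
    def index_1se(self) -> int:
        imin = self.index_min
        bound = self.mean_mse[imin] + self.se_mse[imin]
        ok = np.flatnonzero(self.mean_mse[: imin + 1] <= bound)
        return int(ok[0])  # lambda_seq decreases, so the first hit is the largest lambda

    @property
    def lambda_1se(self) -> float:
        """Largest lambda with CV MSE within one SE of the minimum."""
        return float(self.lambda_seq[self.index_1se])

    def index_for(self, criterion: str) -> int:
        if criterion == "min":
            return self.index_min
        if criterion == "1se":
            return self.index_1se
        raise ValueError("criterion must be 'min' or '1se'")


@dataclass
class SelectionResult:
    """Variables selected at the tuned lambda."""

    criterion: str
    lambda_star: float
    lambda_index: int
    selected: np.ndarray  # 0-based indices of nonzero penalized coefficients
    coefficients: np.ndarray
    intercept: float


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition of ``n`` samples into ``k`` near-equal folds.

    Returns an integer vector of fold labels in ``0..k-1``; fold sizes
    differ by at most one.  Deterministic given ``seed``.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D5]))
    ids = np.resize(np.arange(k), n)
    rng.shuffle(ids)
    return ids


def cv_path(
    X,
    y,
    alpha: float,
    k: int = 10,
    config: SolverConfig | None = None,
    penalty_factors=None,
    seed: int = 0,
    lambda_seq=None,
) -> CVResult:
    """k-fold cross-validated MSE at every lambda of the path.

    For each fold the path is fitted on the other k-1 folds (warm-started
    coordinate descent on the shared full-data lambda grid) and squared
    errors are collected on the held-out fold; ``mean_mse`` averages over
    all n held-out errors and ``se_mse`` is the standard error of the k
    fold-level MSEs.
    """
    config = config or SolverConfig()
    if isinstance(X, GenotypeMatrix):
        X = X.values
    X = np.asarray(X)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if lambda_seq is None:
        lambda_seq = lambda_path(X, y, alpha, config, penalty_factors)
    fold_ids = make_folds(n, k, seed)
    K = len(lambda_seq)
    sq_err = np.empty((n, K))
    fold_mse = np.empty((k, K))
    for f in range(k):
        test = fold_ids == f
        train = ~test
        if np.std(y[train]) == 0:
            import warnings

            warnings.warn(f"fold {f} has constant training response; skipped")
            fold_mse[f] = np.nan
            sq_err[test] = np.nan
            continue
        fit = fit_path(X[train], y[train], alpha, lambda_seq, penalty_factors, config)
        pred = fit.intercepts[None, :] + np.asarray(X[test], dtype=float) @ fit.coefs
        err = (y[test, None] - pred) ** 2
        sq_err[test] = err
        fold_mse[f] = err.mean(axis=0)
    mean_mse = np.nanmean(sq_err, axis=0)
    se_mse = np.nanstd(fold_mse, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(fold_mse[:, 0])))
    return CVResult(
        lambda_seq=np.asarray(lambda_seq, dtype=float),
        mean_mse=mean_mse,
        se_mse=se_mse,
        fold_ids=fold_ids,
        seed=int(seed),
    )


def select_variables(fit: PathFit, cv: CVResult, criterion: str = "1se") -> SelectionResult:
    """Nonzero penalized coefficients at the CV-tuned lambda.

    The tuned lambda lies on the shared grid, so coefficients are read
    straight off the path fit; unpenalized covariate columns are never
    reported as selections.
    """
    idx = cv.index_for(criterion)
    if len(fit.lambda_seq) != len(cv.lambda_seq) or not np.allclose(
        fit.lambda_seq, cv.lambda_seq
    ):
        # snap to the nearest lambda on the fit's grid
        idx = int(np.argmin(np.abs(np.log(fit.lambda_seq) - np.log(cv.lambda_seq[idx]))))
    return SelectionResult(
        criterion=criterion,
        lambda_star=float(fit.lambda_seq[idx]),
        lambda_index=idx,
        selected=fit.nonzero(idx),
        coefficients=fit.coefs[:, idx].copy(),
        intercept=float(fit.intercepts[idx]),
    )


def repeated_cv_lambda(
    X,
    y,
    alpha: float,
    runs: int = 10,
    k: int = 10,
    criterion: str = "1se",
    seeds=None,
    config: SolverConfig | None = None,
    penalty_factors=None,
) -> float:
    """Arithmetic mean of the tuned lambda over repeated CV runs.

    Each run redraws the fold partition; the averaged lambda is used as-is
    (not snapped to the grid) for a final full-data refit.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if seeds is None:
        seeds = list(range(runs))
    if len(seeds) != runs:
        raise ValueError("need one seed per run")
    config = config or SolverConfig()
    lambda_seq = lambda_path(X, y, alpha, config, penalty_factors)
    stars = []
    for s in seeds:
        cv = cv_path(
            X, y, alpha, k=k, config=config, penalty_factors=penalty_factors,
            seed=int(s), lambda_seq=lambda_seq,
        )
        stars.append(cv.lambda_seq[cv.index_for(criterion)])
    return float(np.mean(stars))
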