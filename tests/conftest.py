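import numpy as np
import pytest

from gwaselect.containers import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes(rng):
    """60 x 40 Binomial(2, 0.5) genotype matrix with no structure."""
    vals = rng.binomial(2, 0.5, size=(60, 40)).astype(np.int8)
    return GenotypeMatrix.from_values(vals)


def fista_enet(X, y, lam, alpha, n_steps=200_000, tol=1e-14):
    """High-precision proximal-gradient (FISTA) oracle for the elastic net.

    Minimizes (1/2n)||y_c - X beta||^2 + lam*(alpha*|beta|_1
    + (1-alpha)/2*|beta|_2^2) for standardized X and centered y; kept
    independent of the coordinate-descent implementation under test.
    """
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n + lam * (1 - alpha)
    beta = np.zeros(p)
    zcur = beta.copy()
    t = 1.0
    for _ in range(n_steps):
        grad = -X.T @ (y - X @ zcur) / n + lam * (1 - alpha) * zcur
        w = zcur - grad / L
        thr = lam * alpha / L
        beta_new = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z_new = beta_new + (t - 1) / t_new * (beta_new - beta)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta, zcur, t = beta_new, z_new, t_new
    return beta


def enet_objective(X, y, beta, lam, alpha):
    n = X.shape[0]
    r = y - X @ beta
    return 0.5 * r @ r / n + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * beta @ beta)
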