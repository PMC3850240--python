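"""Eigenvector covariates for population-structure correction.

Ancestry-driven genotype correlation between individuals confounds
association scans; a standard correction enters the leading eigenvectors
of a genetic-similarity matrix as fixed (unpenalized) covariates.  This
module implements a spectral-graph embedding: individuals are vertices of
a weighted graph whose weights are a nonnegative rescaling of the
standardized-genotype inner products, and the embedding uses the top
eigenvectors of the symmetrically normalized weight matrix
D^{-1/2} W D^{-1/2} (the complement of the normalized Laplacian), with
the trivial constant-direction eigenvector dropped.  How many eigenvectors
are "significant" is calibrated by simulation: each SNP column is permuted
independently across individuals to destroy structure while keeping
allele frequencies, and observed eigenvalues are compared with the max of
their null counterparts.

A plain PCA of standardized genotypes is available as an alternative
embedding (``method="pca"`` in :func:`eigenvector_covariates`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = [
    "CovariateMatrix",
    "similarity_matrix",
    "spectral_eigenvectors",
    "n_significant",
    "eigenvector_covariates",
]


@dataclass
class CovariateMatrix:
    """Orthonormal eigenvector covariates with their eigenvalues."""

    vectors: np.ndarray  # n x q, orthonormal columns
    eigenvalues: np.ndarray  # length q, descending
    n_significant: int = 0

    @property
    def q(self) -> int:
        return self.vectors.shape[1]


def _geno_values(G) -> np.ndarray:
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    return np.asarray(X, dtype=np.float64)


def _standardized(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def similarity_matrix(G) -> np.ndarray:
    """Nonnegative genetic-similarity weights between individuals.

    The raw similarity is the genomic-relationship-style inner product of
    standardized genotypes, S = Z Z' / p; weights are then shifted and
    scaled linearly onto [0, 1] (off-diagonal range) so the matrix is a
    valid graph weight matrix.  Symmetric by construction; identical
    individuals attain the maximal off-diagonal weight.
    """
    X = _geno_values(G)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    Z = _standardized(X)
    S = Z @ Z.T / X.shape[1]
    S = (S + S.T) / 2.0
    off = ~np.eye(n, dtype=bool)
    lo, hi = S[off].min(), S[off].max()
    span = hi - lo if hi > lo else 1.0
    W = (S - lo) / span
    np.fill_diagonal(W, 1.0)
    return W


def spectral_eigenvectors(W: np.ndarray, q: int) -> CovariateMatrix:
    """Top-q eigenvectors of the normalized weight matrix.

    Computes the leading eigenpairs of D^{-1/2} W D^{-1/2} (D the degree
    matrix), drops the trivial leading eigenvector (constant direction
    after normalization), and returns the next q orthonormal vectors.
    Signs are fixed so each vector's first nonzero entry is positive.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n) or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be a symmetric square matrix")
    if q >= n:
        raise ValueError("q must be smaller than the number of individuals")
    d = W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("graph has an isolated vertex (zero degree)")
    dm = 1.0 / np.sqrt(d)
    M = dm[:, None] * W * dm[None, :]
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial top eigenvector (proportional to sqrt(d))
    vecs = evecs[:, 1 : q + 1]
    vals = evals[1 : q + 1]
    for k in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, k]) > 1e-12)
        if len(nz) and vecs[nz[0], k] < 0:
            vecs[:, k] = -vecs[:, k]
    return CovariateMatrix(vectors=vecs, eigenvalues=vals)


def n_significant(G, n_null_sims: int = 10, seed: int = 0, q_max: int = 20) -> int:
    """Number of eigenvalues exceeding a permutation-null threshold.

    For each null simulation every SNP column is permuted independently
    across individuals (structure destroyed, allele frequencies kept), the
    spectral eigenvalues are recomputed, and the observed k-th eigenvalue
    is called significant if it exceeds the maximum k-th null eigenvalue
    over all simulations.  Counting stops at the first non-significant
    rank.
    """
    if n_null_sims < 1:
        raise ValueError("need at least one null simulation")
    X = _geno_values(G)
    n = X.shape[0]
    q = min(q_max, n - 2)
    obs = spectral_eigenvectors(similarity_matrix(X), q).eigenvalues
    ss = np.random.SeedSequence([int(seed), 0x9057])
    null_max = np.full(q, -np.inf)
    for child in ss.spawn(n_null_sims):
        rng = np.random.default_rng(child)
        Xp = X.copy()
        for j in range(X.shape[1]):
            rng.shuffle(Xp[:, j])
        ev = spectral_eigenvectors(similarity_matrix(Xp), q).eigenvalues
        null_max = np.maximum(null_max, ev)
    sig = obs > null_max
    k = 0
    while k < q and sig[k]:
        k += 1
    return k


def eigenvector_covariates(
    G, q: int, method: str = "spectral", n_null_sims: int = 0, seed: int = 0
) -> CovariateMatrix:
    """Convenience wrapper returning q covariates by either embedding.

    ``method="spectral"`` uses the normalized graph embedding above;
    ``method="pca"`` returns the top principal components of standardized
    genotypes (left singular vectors).  If ``n_null_sims > 0`` the
    advisory ``n_significant`` count is computed and attached.
    """
    if method == "spectral":
        cov = spectral_eigenvectors(similarity_matrix(G), q)
    elif method == "pca":
        Z = _standardized(_geno_values(G))
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        vecs = U[:, :q]
        for k in range(vecs.shape[1]):
            nz = np.flatnonzero(np.abs(vecs[:, k]) > 1e-12)
            if len(nz) and vecs[nz[0], k] < 0:
                vecs[:, k] = -vecs[:, k]
        cov = CovariateMatrix(vectors=vecs, eigenvalues=(s[:q] ** 2) / Z.shape[0])
    else:
        raise ValueError("method must be 'spectral' or 'pca'")
    if n_null_sims > 0:
        cov.n_significant = n_significant(G, n_null_sims, seed)
    return cov
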