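"""Numba kernel for cyclic coordinate descent over an elastic-net path.

Works on the standardized scale: rows of ``XT`` (a C-contiguous p x n
matrix, i.e. the transpose of the standardized design) have zero mean and
unit 1/n-variance, and ``y`` is centered.  The objective minimized at each
lambda is

    (1 / 2n) * ||y - X beta||^2
        + lambda * sum_j pf_j * (alpha * |beta_j| + (1 - alpha)/2 * beta_j^2)

The solver keeps an ever-active set: coordinates are swept to convergence,
then the full gradient is checked for KKT violations and any violators are
admitted; a lambda is converged when a sweep satisfies
``max_j (delta beta_j)^2 < tol * var(y)`` (the scaled squared-change
criterion used by coordinate-descent GLM software) and no excluded
coordinate violates its KKT bound.  Warm starts carry both the
coefficients and the ever-active set down the path.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@numba.njit(cache=True)
def ccd_path(XT, y, lambdas, alpha, pf, tol, max_iter):
    """Solve the elastic-net path by cyclic coordinate descent.

    Returns (betas[K, p], n_iter[K], converged[K]) on the standardized
    scale.  ``max_iter`` caps the number of coordinate sweeps per lambda;
    hitting the cap flags that lambda as unconverged but is not fatal.
    """
    p, n = XT.shape
    K = lambdas.shape[0]
    betas = np.zeros((K, p))
    n_iter = np.zeros(K, dtype=np.int64)
    converged = np.zeros(K, dtype=np.bool_)
    vy = np.dot(y, y) / n
    if vy <= 0.0:
        vy = 1.0
    dtol = tol * vy  # threshold on max squared coefficient change per sweep

    beta = np.zeros(p)
    r = y.copy()
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        if pf[j] == 0.0:
            active[j] = True  # unpenalized covariates always in the model

    for k in range(K):
        lam = lambdas[k]
        it = 0
        done = False
        while not done:
            # sweep the active set to convergence
            while it < max_iter:
                maxd = 0.0
                for j in range(p):
                    if not active[j]:
                        continue
                    bj = beta[j]
                    z = np.dot(XT[j], r) / n + bj
                    bn = _soft(z, lam * alpha * pf[j]) / (1.0 + lam * (1.0 - alpha) * pf[j])
                    d = bn - bj
                    if d != 0.0:
                        beta[j] = bn
                        r -= d * XT[j]
                        if d * d > maxd:
                            maxd = d * d
                it += 1
                if maxd < dtol:
                    break
            if it >= max_iter:
                break
            # KKT screen over excluded coordinates
            g = np.dot(XT, r) / n
            n_viol = 0
            for j in range(p):
                if active[j]:
                    continue
                if abs(g[j]) > lam * alpha * pf[j] + 1e-12:
                    active[j] = True
                    n_viol += 1
            if n_viol == 0:
                done = True
        betas[k] = beta
        n_iter[k] = it
        converged[k] = done
    return betas, n_iter, converged
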