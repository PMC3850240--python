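"""Single-marker association scan, Bonferroni selection, and local fdr.

The scan regresses the phenotype on each SNP separately (ordinary least
squares with an intercept and optional fixed covariates) and reports the
slope, its standard error, the t statistic and a two-sided p-value per
SNP.  Two multiplicity treatments are provided:

* Bonferroni: keep SNPs with p < family_alpha / p_total.
* Local false discovery rate (Efron): transform p-values to z-scores,
  estimate the marginal density f(z) by Poisson regression of histogram
  counts on a natural-spline basis, fit an empirical null N(delta0,
  sigma0^2) and null proportion pi0 by maximum likelihood on the central
  z-values, and report fdr(z) = pi0 * f0(z) / f(z), flagging SNPs with
  fdr < 0.2 (the conventional threshold).

The z transform defaults to the signed form z = sign(slope) *
|Phi^-1(p/2)|, which preserves the two-tailed structure; the literal
one-sided form z = Phi^-1(p) is available via ``signed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "MarkerScanResult",
    "LocalFdrResult",
    "marker_scan",
    "bonferroni_select",
    "z_transform",
    "local_fdr",
]

P_CLIP = 1e-15


@dataclass
class MarkerScanResult:
    """Per-SNP OLS slope, standard error, t statistic and p-value."""

    slope: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    df_resid: int
    zero_variance: np.ndarray  # SNPs with no genotype variation (p set to 1)

    def __len__(self) -> int:
        return len(self.slope)


@dataclass
class LocalFdrResult:
    """Empirical-null local false discovery rates for a z-value vector."""

    z: np.ndarray
    delta0: float
    sigma0: float
    pi0: float
    fdr: np.ndarray
    threshold: float
    flagged: np.ndarray  # indices with fdr < threshold


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out the column space of C (which includes the intercept)."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def marker_scan(G, y, covariates=None) -> MarkerScanResult:
    """OLS of the phenotype on each SNP (plus intercept and covariates).

    Equivalent to fitting ``y ~ 1 + covariates + x_j`` per SNP j; computed
    by projecting the covariates out of both sides (Frisch-Waugh), which
    vectorizes the scan across all SNPs.  Zero-variance SNPs get slope 0
    and p = 1 and are flagged.
    """
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if (np.asarray(X) == MISSING).any():
        raise ValueError("genotypes contain missing values; impute first (qc_filter)")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.hstack([C, cov])
    q = C.shape[1]
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    Xr = _residualize(X, C)
    yr = _residualize(y[:, None], C).ravel()

    sxx = np.einsum("ij,ij->j", Xr, Xr)
    zero_var = sxx <= n * 1e-12
    sxx_safe = np.where(zero_var, 1.0, sxx)
    slope = (Xr.T @ yr) / sxx_safe
    # residual sum of squares of the full per-SNP model
    syy = float(yr @ yr)
    rss = syy - slope**2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        # se == 0 with a nonzero slope is an exact fit: p -> 0
        t = np.where(se > 0, slope / se, np.where(slope != 0, np.inf, 0.0))
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    slope[zero_var] = 0.0
    se[zero_var] = 0.0
    t[zero_var] = 0.0
    p_val[zero_var] = 1.0
    p_val = np.clip(p_val, 0.0, 1.0)
    return MarkerScanResult(
        slope=slope, se=se, t=t, p_value=p_val, df_resid=df, zero_variance=zero_var
    )


def bonferroni_select(scan: MarkerScanResult, family_alpha: float = 0.05) -> np.ndarray:
    """SNP indices with p below the Bonferroni-corrected threshold."""
    m = len(scan)
    if m == 0:
        return np.array([], dtype=np.int64)
    return np.flatnonzero(scan.p_value < family_alpha / m)


def z_transform(p_values, slopes=None, signed: bool = True) -> np.ndarray:
    """Map p-values to z-scores through the standard-normal quantile.

    With ``signed=True`` (default) two-sided p-values become
    z = sign(slope) * |Phi^-1(p/2)|, preserving effect direction; with
    ``signed=False`` the literal z = Phi^-1(p) is returned.  p-values are
    clipped to [1e-15, 1 - 1e-15] before the transform.
    """
    p = np.clip(np.asarray(p_values, dtype=float), P_CLIP, 1.0 - P_CLIP)
    if (np.asarray(p_values) <= 0).any():
        raise ValueError("p-values must be positive")
    if not signed:
        return stats.norm.ppf(p)
    if slopes is None:
        raise ValueError("signed z-transform needs the slopes for their signs")
    sign = np.where(np.asarray(slopes) < 0, -1.0, 1.0)
    return sign * np.abs(stats.norm.ppf(p / 2.0))


def _null_mle(z_center: np.ndarray, a: float, b: float, n_total: int):
    """Joint MLE of (delta0, sigma0, pi0) for the empirical null.

    The n0 central z-values are modeled as draws from N(delta0, sigma0^2)
    truncated to [a, b]; the count n0 out of n_total carries the Binomial
    term with success probability pi0 * P0([a, b]).  Jointly these give
    the log-likelihood (up to constants)

        sum_center log phi((z - d)/s)/s  +  n0 log pi0
            + (n_total - n0) log(1 - pi0 * P0)

    whose maximizer pins sigma0 down even though the window-shape part
    alone is nearly flat in sigma0.
    """
    from scipy.optimize import minimize

    n0 = len(z_center)
    n1 = n_total - n0

    def nll(theta):
        d, log_s, logit_p = theta
        s = np.exp(log_s)
        pi0 = 1.0 / (1.0 + np.exp(-logit_p))
        p0 = stats.norm.cdf(b, d, s) - stats.norm.cdf(a, d, s)
        tail = 1.0 - pi0 * p0
        if p0 <= 1e-12 or tail <= 1e-12:
            return 1e12
        ll = np.sum(stats.norm.logpdf(z_center, d, s)) + n0 * np.log(pi0) + n1 * np.log(tail)
        return -ll

    x0 = np.array([np.median(z_center), 0.0, 3.0])
    res = minimize(nll, x0=x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    d, log_s, logit_p = res.x
    return float(d), float(np.exp(log_s)), float(1.0 / (1.0 + np.exp(-logit_p)))


def local_fdr(
    z,
    threshold: float = 0.2,
    bins: int = 120,
    df: int = 7,
    null_fit_range: float = 0.5,
) -> LocalFdrResult:
    """Efron-style local false discovery rate with an empirical null.

    f(z) is estimated by Poisson regression of histogram counts (``bins``
    equal-width bins) on a natural cubic spline basis with ``df`` degrees
    of freedom, normalized to a density.  The empirical null
    N(delta0, sigma0^2) and the null proportion pi0 are fitted jointly by
    maximum likelihood on the central ``null_fit_range`` proportion of the
    z-values (truncated-normal shape plus the Binomial window-count term).
    fdr(z) = pi0 * phi((z - delta0)/sigma0)/sigma0 / f(z), clipped to
    [0, 1].
    """
    z = np.asarray(z, dtype=float).ravel()
    if len(z) < bins:
        raise ValueError("need at least as many z-values as histogram bins")
    lo = (1.0 - null_fit_range) / 2.0
    a, b = np.quantile(z, [lo, 1.0 - lo])
    if b <= a:
        raise ValueError("degenerate central window for the empirical null")
    center = z[(z >= a) & (z <= b)]
    delta0, sigma0, pi0 = _null_mle(center, a, b, len(z))
    if pi0 > 1.0:  # kept for safety; the logistic parametrization bounds pi0
        import warnings

        warnings.warn(f"pi0 estimate {pi0:.3f} > 1; clipped to 1")
        pi0 = 1.0

    # marginal density by Poisson spline regression on histogram counts
    counts, edges = np.histogram(z, bins=bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    import statsmodels.api as sm
    from patsy import dmatrix

    basis = dmatrix("cr(x, df=df) - 1", {"x": mids, "df": df}, return_type="dataframe")
    design = sm.add_constant(np.asarray(basis))
    fit = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    dens_bin = fit.mu / (len(z) * width)

    basis_z = dmatrix(
        "cr(x, df=df) - 1",
        {"x": np.clip(z, mids[0], mids[-1]), "df": df},
        return_type="dataframe",
    )
    # natural splines extrapolate linearly; clamping z to the bin-mid range
    # keeps the log-density bounded in the extreme tails
    eta = fit.params[0] + np.asarray(basis_z) @ fit.params[1:]
    f_z = np.exp(eta) / (len(z) * width)
    f_z = np.maximum(f_z, 1e-300)

    f0_z = stats.norm.pdf(z, delta0, sigma0)
    fdr = np.clip(pi0 * f0_z / f_z, 0.0, 1.0)
    return LocalFdrResult(
        z=z,
        delta0=delta0,
        sigma0=sigma0,
        pi0=float(pi0),
        fdr=fdr,
        threshold=float(threshold),
        flagged=np.flatnonzero(fdr < threshold),
    )
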