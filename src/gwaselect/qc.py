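"""Genotype quality-control filters and mean imputation.

Mirrors the standard SNP-chip preprocessing chain: drop SNPs with call
rate below 90%, minor allele frequency below 1% (computed on called
genotypes after the call-rate filter), or significant deviation from
Hardy-Weinberg equilibrium (one-df Pearson chi-square on the observed
genotype counts, p < 1e-5); then replace remaining missing entries with
the SNP's mean genotype (twice the allele frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import MISSING, GenotypeMatrix

__all__ = ["QCReport", "qc_filter", "hwe_pvalues"]


@dataclass
class QCReport:
    n_snps_in: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_imputed_entries: int
    n_snps_out: int


def hwe_pvalues(values: np.ndarray) -> np.ndarray:
    """One-df Pearson chi-square HWE p-value per SNP column.

    Observed genotype counts (n0, n1, n2) on called entries are compared
    with Hardy-Weinberg expectations at the observed allele frequency.
    Monomorphic columns get p = 1.
    """
    called = values != MISSING
    n = called.sum(axis=0).astype(float)
    n1 = ((values == 1) & called).sum(axis=0)
    n2 = ((values == 2) & called).sum(axis=0)
    n0 = n - n1 - n2
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (2 * n2 + n1) / (2 * n)  # counted-allele frequency
        e0 = n * (1 - q) ** 2
        e1 = n * 2 * q * (1 - q)
        e2 = n * q**2
        chi2 = np.zeros(values.shape[1])
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 += term
    p = stats.chi2.sf(chi2, df=1)
    mono = (q <= 0) | (q >= 1)
    p[mono] = 1.0
    return p


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate, MAF and HWE filters, then mean-impute.

    Filters are applied in that order (MAF on the call-rate survivors,
    HWE on the MAF survivors); imputation replaces missing entries of the
    retained SNPs with the column mean genotype, so the returned matrix
    is float-valued wherever imputation occurred.
    """
    values = G.values
    n, p_in = values.shape
    called = values != MISSING

    callrate = called.mean(axis=0)
    keep_cr = callrate >= callrate_min
    n_rm_cr = int(p_in - keep_cr.sum())

    n1 = ((values == 1) & called).sum(axis=0)
    n2 = ((values == 2) & called).sum(axis=0)
    ncall = called.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ncall > 0, (2 * n2 + n1) / (2 * ncall), 0.0)
    maf = np.minimum(q, 1 - q)
    keep_maf = keep_cr & (maf >= maf_min)
    n_rm_maf = int(keep_cr.sum() - keep_maf.sum())

    hwe_p = hwe_pvalues(values)
    keep = keep_maf & (hwe_p >= hwe_p_min)
    n_rm_hwe = int(keep_maf.sum() - keep.sum())

    if not keep.any():
        raise ValueError("quality control removed every SNP")

    sub = values[:, keep].astype(np.float64)
    miss = sub == MISSING
    n_imp = int(miss.sum())
    if n_imp:
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, sub).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        sub = np.where(miss, col_mean[None, :], sub)

    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.values = sub
    out.snp_ids = G.snp_ids[keep].copy()
    out.positions = G.positions[keep].copy()
    out.sample_ids = G.sample_ids.copy()
    report = QCReport(
        n_snps_in=p_in,
        n_removed_callrate=n_rm_cr,
        n_removed_maf=n_rm_maf,
        n_removed_hwe=n_rm_hwe,
        n_imputed_entries=n_imp,
        n_snps_out=int(keep.sum()),
    )
    return out, report
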