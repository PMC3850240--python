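"""Readers and writers for the plain-text formats used by the pipeline.

Genotypes travel either as PLINK ``.raw`` dialect (whitespace-delimited,
six leading columns FID IID PAT MAT SEX PHENOTYPE, then one column per
SNP with genotypes 0/1/2 and missing as NA; SNP headers may carry a
counted-allele suffix like ``snp12_A``) or as a plain CSV matrix (header
row of SNP ids, one row per individual with a leading sample-id column).
Phenotypes, covariates, causal sets and result tables are tab-delimited
text with a header row.  Floats are written with %.6g so reruns with the
same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .cv import SelectionResult
from .association import MarkerScanResult
from .evaluate import EvaluationSummary

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "write_covariates",
    "write_causal",
    "read_causal",
    "write_selection",
]

RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
FLOAT_FMT = "%.6g"


def _validate_geno(df: pd.DataFrame, path) -> np.ndarray:
    vals = df.to_numpy()
    arr = np.full(vals.shape, MISSING, dtype=np.int8)
    bad = None
    with np.errstate(invalid="ignore"):
        num = pd.to_numeric(pd.Series(vals.ravel()), errors="coerce").to_numpy()
    isna = np.isnan(num)
    okvals = np.isin(num, (0.0, 1.0, 2.0))
    good = isna | okvals
    if not good.all():
        flat = int(np.flatnonzero(~good)[0])
        r, c = divmod(flat, vals.shape[1])
        raise ValueError(
            f"{path}: genotype {vals[r, c]!r} at data row {r + 1}, "
            f"SNP column {df.columns[c]!r} is not 0/1/2 or missing"
        )
    arr = np.where(isna, MISSING, np.nan_to_num(num, nan=MISSING)).astype(np.int8)
    return arr.reshape(vals.shape)


def read_genotypes(path, format: str = "raw") -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Read a genotype matrix; returns (genotypes, phenotype-or-None).

    ``format="raw"`` expects the PLINK .raw dialect (whitespace-delimited)
    and also returns the PHENOTYPE column when it is not all missing;
    ``format="csv"`` expects a comma-separated matrix with a sample_id
    column and returns None for the phenotype.
    """
    path = Path(path)
    if format == "raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_lead = [c for c in RAW_LEAD if c not in df.columns]
        if missing_lead:
            raise ValueError(f"{path}: not PLINK .raw dialect; missing columns {missing_lead}")
        snp_cols = [c for c in df.columns if c not in RAW_LEAD]
        values = _validate_geno(df[snp_cols], path)
        snp_ids = np.array([c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols])
        if len(np.unique(snp_ids)) != len(snp_ids):
            snp_ids = np.array(snp_cols)  # suffix-stripping collided; keep raw headers
        pheno = df["PHENOTYPE"].to_numpy(dtype=float)
        if np.isnan(pheno).all():
            pheno = None
        G = GenotypeMatrix(
            values=values,
            snp_ids=snp_ids,
            positions=np.arange(1, len(snp_ids) + 1),
            sample_ids=df["IID"].astype(str).to_numpy(),
        )
        return G, pheno
    if format == "csv":
        df = pd.read_csv(path, na_values=["NA"])
        id_col = df.columns[0]
        values = _validate_geno(df.drop(columns=[id_col]), path)
        G = GenotypeMatrix(
            values=values,
            snp_ids=np.asarray(df.columns[1:]),
            positions=np.arange(1, df.shape[1]),
            sample_ids=df[id_col].astype(str).to_numpy(),
        )
        return G, None
    raise ValueError("format must be 'raw' or 'csv'")


def write_genotypes(G: GenotypeMatrix, path, phenotype=None, format: str = "raw") -> None:
    """Write genotypes as PLINK .raw dialect or CSV (see read_genotypes)."""
    path = Path(path)
    vals = G.values
    out = pd.DataFrame(
        np.where(vals == MISSING, np.nan, vals),
        columns=[f"{s}_A" for s in G.snp_ids] if format == "raw" else list(G.snp_ids),
    )
    if format == "raw":
        lead = pd.DataFrame(
            {
                "FID": G.sample_ids,
                "IID": G.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": phenotype if phenotype is not None else np.nan,
            }
        )
        df = pd.concat([lead, out], axis=1)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)
    elif format == "csv":
        out.insert(0, "sample_id", G.sample_ids)
        out.to_csv(path, index=False, na_rep="NA", float_format=FLOAT_FMT)
    else:
        raise ValueError("format must be 'raw' or 'csv'")


def read_phenotype(path) -> np.ndarray:
    """Phenotype TSV: columns sample_id, value."""
    df = pd.read_csv(path, sep="\t")
    return df["value"].to_numpy(dtype=float)


def write_phenotype(y, path, sample_ids=None) -> None:
    y = np.asarray(y, dtype=float)
    ids = sample_ids if sample_ids is not None else [f"id{i + 1}" for i in range(len(y))]
    pd.DataFrame({"sample_id": ids, "value": y}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_covariates(path) -> np.ndarray:
    """Covariate TSV: sample_id column followed by one column per covariate."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 1:].to_numpy(dtype=float)


def write_covariates(C, path, sample_ids=None) -> None:
    C = np.atleast_2d(np.asarray(C, dtype=float))
    ids = sample_ids if sample_ids is not None else [f"id{i + 1}" for i in range(C.shape[0])]
    df = pd.DataFrame(C, columns=[f"ev{k + 1}" for k in range(C.shape[1])])
    df.insert(0, "sample_id", ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_causal(G: GenotypeMatrix, causal, path) -> None:
    """Causal-set sidecar TSV: snp_id, position, ld_class."""
    rows = [
        {
            "snp_id": G.snp_ids[j],
            "position": int(G.positions[j]),
            "ld_class": causal.ld_class.get(int(j), "sorted"),
        }
        for j in causal.indices
    ]
    pd.DataFrame(rows, columns=["snp_id", "position", "ld_class"]).to_csv(
        path, sep="\t", index=False
    )


def read_causal(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_selection(result, path, snp_ids=None) -> None:
    """Write a selection, marker-scan or evaluation result as TSV.

    Column order is deterministic and floats use %.6g, so identical
    inputs give byte-identical files.
    """
    path = Path(path)
    if isinstance(result, SelectionResult):
        sel = result.selected
        df = pd.DataFrame(
            {
                "snp": np.asarray(snp_ids)[sel] if snp_ids is not None else sel,
                "index": sel,
                "coefficient": result.coefficients[sel],
            }
        )
        df.insert(0, "criterion", result.criterion)
        df.insert(1, "lambda", result.lambda_star)
    elif isinstance(result, MarkerScanResult):
        df = pd.DataFrame(
            {
                "snp": snp_ids if snp_ids is not None else np.arange(len(result)),
                "slope": result.slope,
                "se": result.se,
                "t": result.t,
                "p_value": result.p_value,
                "zero_variance": result.zero_variance.astype(int),
            }
        )
    elif isinstance(result, EvaluationSummary):
        df = result.table
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
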