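"""Core in-memory containers shared across the package.

Genotypes are held as an ``n x p`` integer matrix coded 0/1/2 (minor-allele
count), with ``-1`` as the missing-value sentinel prior to imputation.
Column indices are 0-based everywhere in the API; the 1-based marker
coordinate lives in ``positions``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """n individuals by p SNPs, entries in {0, 1, 2} (or -1 for missing).

    Parameters
    ----------
    values : ndarray of shape (n, p), integer dtype
    snp_ids : array of unique SNP identifiers, length p
    positions : 1-based integer marker coordinates, length p
    sample_ids : individual identifiers, length n
    """

    values: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    sample_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.snp_ids = np.asarray(self.snp_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.snp_ids) != p or len(self.positions) != p:
            raise ValueError("snp_ids/positions length must equal number of SNPs")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal number of individuals")
        if len(np.unique(self.snp_ids)) != p:
            raise ValueError("snp_ids must be unique")
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype entry at row {bad[0]}, column {bad[1]} is not in "
                f"{{0, 1, 2}} or missing"
            )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            self.snp_ids.copy(),
            self.positions.copy(),
            self.sample_ids.copy(),
        )

    @classmethod
    def from_values(cls, values: np.ndarray, prefix: str = "snp") -> "GenotypeMatrix":
        """Wrap a raw 0/1/2 matrix with generated ids and coordinates."""
        values = np.asarray(values)
        n, p = values.shape
        return cls(
            values=values,
            snp_ids=np.array([f"{prefix}{j + 1}" for j in range(p)]),
            positions=np.arange(1, p + 1),
            sample_ids=np.array([f"id{i + 1}" for i in range(n)]),
        )

    def n_missing(self) -> int:
        return int((self.values == MISSING).sum())


@dataclass
class CausalSet:
    """Known causal SNP columns of a simulated genotype matrix.

    ``indices`` are 0-based columns; ``ld_class`` maps each index to
    ``"sorted"`` (fully phenotype-sorted column) or ``"partially_permuted"``
    (a fraction of entries re-shuffled to weaken LD).
    """

    indices: np.ndarray
    ld_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(sorted(set(int(i) for i in np.asarray(self.indices).ravel())))

    def __len__(self) -> int:
        return len(self.indices)

    def as_set(self) -> set[int]:
        return set(int(i) for i in self.indices)
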