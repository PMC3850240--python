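"""LD-structured genotype/phenotype simulator with known causal SNPs.

The generator reproduces a benchmark design for penalized-regression
variable selection: a bimodal continuous phenotype (half the individuals
drawn from N(2, 1), half from N(-2, 1)) and a large panel of independent
Binomial(2, 0.5) SNPs, of which a small set of "causal" columns is made
strongly associated with the trait by re-assigning each column's genotype
values against the descending phenotype order.  Because every causal column
is sorted against the same phenotype, the causal columns become highly
inter-correlated (mean pairwise r ~ 0.97); partially re-shuffling a
fraction of entries within chosen columns lowers that correlation in a
controlled way (~0.78 when 10 of 25 columns are degraded, ~0.55 when all
are).

Three named settings are provided:

``high``
    25 causal SNPs in 5 blocks of 5, all fully sorted.
``mixed``
    as ``high``, then 25% of entries permuted within each column of the
    first and last blocks (10 of 25 columns degraded).
``low``
    as ``high``, then 25% of entries permuted within every causal column.

All operations are deterministic given their seed; replicate and
per-column streams are derived from one master seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CausalSet, GenotypeMatrix

#: canonical block centers of the 25-causal design on a 50,000-SNP panel
#: (1-based positions); they scale proportionally for other panel sizes.
REFERENCE_CENTERS_25 = (1000, 10_000, 20_000, 30_000, 40_000)
REFERENCE_P = 50_000

SETTING_NAMES = ("high", "mixed", "low")


@dataclass
class SimSetting:
    """Configuration of one simulation replicate.

    ``block_centers`` are 1-based SNP positions; each block spans
    ``block_size`` consecutive columns centered there.  ``degrade_columns``
    lists the 0-based causal columns whose within-column order is partially
    permuted, with ``permute_fraction`` of entries shuffled.
    """

    name: str
    n: int = 1000
    p: int = 50_000
    n_causal: int = 25
    block_size: int = 5
    block_centers: tuple[int, ...] = ()
    permute_fraction: float = 0.25
    seed: int = 0
    degrade_columns: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.name not in SETTING_NAMES:
            raise ValueError(f"unknown setting name {self.name!r}; expected one of {SETTING_NAMES}")
        if self.n % 2 != 0:
            raise ValueError("n must be even (half-high, half-low phenotype design)")
        if not 0.0 <= self.permute_fraction <= 1.0:
            raise ValueError("permute_fraction must lie in [0, 1]")
        if self.n_causal % self.block_size != 0:
            raise ValueError("n_causal must be a multiple of block_size")
        if not self.block_centers:
            self.block_centers = default_block_centers(self.p, self.n_causal, self.block_size)
        if len(self.block_centers) * self.block_size != self.n_causal:
            raise ValueError("n_causal must equal block_size * number of blocks")
        cols = self.causal_columns()
        if cols.min() < 0 or cols.max() >= self.p:
            raise ValueError("causal blocks fall outside 1..p; increase p or move centers")
        if not self.degrade_columns:
            self.degrade_columns = _default_degrade(self.name, cols, self.block_size)

    def causal_columns(self) -> np.ndarray:
        """0-based columns of all causal SNPs, in ascending order."""
        cols = []
        half = self.block_size // 2
        for c in self.block_centers:
            start = (c - 1) - half
            cols.extend(range(start, start + self.block_size))
        return np.asarray(cols, dtype=np.int64)


def default_block_centers(p: int, n_causal: int, block_size: int = 5) -> tuple[int, ...]:
    """Block centers (1-based) for a panel of ``p`` SNPs.

    For the canonical 25-causal design the reference centers
    (1000, 10000, 20000, 30000, 40000) are scaled by ``p / 50000``.  For
    other causal counts, blocks are spread evenly over the panel.
    """
    n_blocks = n_causal // block_size
    if n_blocks == len(REFERENCE_CENTERS_25):
        centers = tuple(int(round(c * p / REFERENCE_P)) for c in REFERENCE_CENTERS_25)
    else:
        centers = tuple(
            int(round((b + 0.5) * p / n_blocks)) for b in range(n_blocks)
        )
    if len(set(centers)) != n_blocks:
        raise ValueError("panel too small: causal blocks collide")
    return centers


def _default_degrade(name: str, causal_cols: np.ndarray, block_size: int) -> tuple[int, ...]:
    if name == "high":
        return ()
    if name == "mixed":
        # first and last blocks: 2 * block_size columns degraded
        return tuple(int(c) for c in np.concatenate([causal_cols[:block_size], causal_cols[-block_size:]]))
    return tuple(int(c) for c in causal_cols)  # low: every causal column


def simulate_base(setting: SimSetting) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the unassociated genotype panel and the bimodal phenotype.

    Genotypes are the entrywise sum of two independent Bernoulli(0.5)
    matrices, i.e. every entry is Binomial(2, 0.5).  The phenotype has its
    first n/2 entries from N(2, 1) and last n/2 from N(-2, 1), unsorted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(setting.seed), 0x5EED]))
    n, p = setting.n, setting.p
    geno = rng.integers(0, 2, size=(n, p), dtype=np.int8)
    geno += rng.integers(0, 2, size=(n, p), dtype=np.int8)
    half = n // 2
    y = np.empty(n)
    y[:half] = rng.normal(2.0, 1.0, size=half)
    y[half:] = rng.normal(-2.0, 1.0, size=n - half)
    return GenotypeMatrix.from_values(geno), y


def embed_causal_block(
    G: GenotypeMatrix, y: np.ndarray, causal: CausalSet, inplace: bool = False
) -> GenotypeMatrix:
    """Sort each causal column so its 2s sit with the high-phenotype half.

    Every causal column keeps its multiset of genotype values but is
    re-assigned in descending order (2s first, then 1s, then 0s) down the
    rows, with rows ranked only by phenotype *group*: the n/2 individuals
    with the highest phenotypes come first, each group in original row
    order.  For the generator output (high half first) this is a plain
    descending sort of the column.

    Two consequences define the benchmark's difficulty and are
    deliberate.  First, all causal columns are sorted against the same row
    order, so their pairwise correlation is near 1 (~0.97, the residual
    randomness being each column's own genotype counts).  Second, the
    assignment ignores the fine phenotype ranking *within* the halves, so
    a causal SNP is a proxy for group membership only (r ~ 0.63 with the
    trait, single-SNP R^2 ~ 0.4) -- the phenotype was generated unsorted
    and stays that way.
    """
    if not inplace:
        G = G.copy()
    y = np.asarray(y, dtype=float)
    if len(y) != G.n:
        raise ValueError("phenotype length does not match genotype rows")
    cols = causal.indices
    if len(cols) and (cols.min() < 0 or cols.max() >= G.p):
        raise IndexError("causal column index out of range")
    half = G.n // 2
    # rows of the high-phenotype group (in original order), then the rest
    high = np.sort(np.argsort(-y, kind="stable")[:half])
    low = np.setdiff1d(np.arange(G.n), high, assume_unique=True)
    order = np.concatenate([high, low])
    for j in cols:
        col = G.values[:, j]
        sorted_vals = np.sort(col)[::-1]  # 2s, then 1s, then 0s
        G.values[order, j] = sorted_vals
    return G


def degrade_ld(
    G: GenotypeMatrix,
    columns,
    fraction: float,
    seed: int,
    inplace: bool = False,
) -> GenotypeMatrix:
    """Randomly permute a fraction of entries within each listed column.

    For each column independently, ``round(fraction * n)`` row positions
    are drawn uniformly without replacement and the values at those
    positions are shuffled among themselves; all other entries are
    untouched.  ``fraction=0`` is the identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not inplace:
        G = G.copy()
    columns = np.asarray(list(columns), dtype=np.int64)
    m = int(round(fraction * G.n))
    if m < 2 or len(columns) == 0:
        return G
    ss = np.random.SeedSequence([int(seed), 0xD16E5])
    for j, child in zip(columns, ss.spawn(len(columns))):
        rng = np.random.default_rng(child)
        rows = rng.choice(G.n, size=m, replace=False)
        shuffled = rows.copy()
        rng.shuffle(shuffled)
        G.values[rows, j] = G.values[shuffled, j]
    return G


def make_setting(
    name: str,
    p: int = 50_000,
    n_causal: int = 25,
    seed: int = 0,
    n: int = 1000,
    permute_fraction: float = 0.25,
) -> tuple[GenotypeMatrix, np.ndarray, CausalSet]:
    """Compose one full replicate of a named correlation setting.

    Runs ``simulate_base`` -> ``embed_causal_block`` -> ``degrade_ld`` and
    records the causal columns with their LD class.
    """
    setting = SimSetting(
        name=name, n=n, p=p, n_causal=n_causal, seed=seed, permute_fraction=permute_fraction
    )
    G, y = simulate_base(setting)
    cols = setting.causal_columns()
    degraded = set(setting.degrade_columns)
    causal = CausalSet(
        indices=cols,
        ld_class={
            int(j): ("partially_permuted" if j in degraded else "sorted") for j in cols
        },
    )
    G = embed_causal_block(G, y, causal, inplace=True)
    if degraded:
        G = degrade_ld(G, sorted(degraded), setting.permute_fraction, seed=setting.seed, inplace=True)
    return G, y, causal


def mean_pairwise_correlation(G: GenotypeMatrix, columns) -> float:
    """Mean of all pairwise Pearson correlations among the given columns."""
    sub = np.asarray(G.values[:, np.asarray(list(columns))], dtype=float)
    R = np.corrcoef(sub, rowvar=False)
    iu = np.triu_indices_from(R, k=1)
    return float(R[iu].mean())
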