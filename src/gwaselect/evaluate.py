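"""Selection-accuracy benchmarking against known causal sets.

Runs the full pipeline (simulate -> path fit -> cross-validate -> select)
over replicates of the named LD settings and a grid of penalty weights,
and summarizes per cell the median and SD of correct and false-positive
selection counts plus the mean and SD of the cross-validated MSE at the
tuned lambda -- the layout of the benchmark's selection-accuracy table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import CausalSet
from .cv import cv_path, select_variables
from .simulate import make_setting
from .solver import SolverConfig, fit_path, lambda_path

__all__ = [
    "EvaluationSummary",
    "score_selection",
    "run_replicate",
    "replicate_table1",
    "overlap_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationSummary:
    """Per (setting, alpha, criterion) selection-accuracy summaries."""

    table: pd.DataFrame
    n_causal: int
    p: int
    n_reps: int
    failed: list = field(default_factory=list)

    def cell(self, setting: str, alpha: float, criterion: str) -> pd.Series:
        t = self.table
        m = (
            (t["setting"] == setting)
            & (np.isclose(t["alpha"], alpha))
            & (t["criterion"] == criterion)
        )
        return t[m].iloc[0]


def score_selection(selected, causal: CausalSet | set) -> tuple[int, int]:
    """(number of causal columns selected, number of false positives)."""
    sel = set(int(i) for i in np.asarray(list(selected)).ravel()) if len(list(selected)) else set()
    cs = causal.as_set() if isinstance(causal, CausalSet) else set(causal)
    n_correct = len(sel & cs)
    return n_correct, len(sel) - n_correct


def run_replicate(
    setting: str,
    alpha: float,
    seed: int,
    p: int = 5000,
    n_causal: int = 25,
    k: int = 10,
    config: SolverConfig | None = None,
    criteria: tuple[str, ...] = ("min", "1se"),
) -> dict:
    """One simulate -> fit -> CV -> select -> score pass.

    Returns per-criterion correct/false-positive counts, the CV MSE at
    the tuned lambda, and the selected index sets.
    """
    config = config or SolverConfig()
    G, y, causal = make_setting(setting, p=p, n_causal=n_causal, seed=seed)
    lam = lambda_path(G.values, y, alpha, config)
    fit = fit_path(G.values, y, alpha, lam, config=config)
    cv = cv_path(G.values, y, alpha, k=k, config=config, seed=seed + 7919, lambda_seq=lam)
    out = {"setting": setting, "alpha": alpha, "seed": seed}
    for crit in criteria:
        sel = select_variables(fit, cv, crit)
        n_corr, n_fp = score_selection(sel.selected, causal)
        out[crit] = {
            "correct": n_corr,
            "false_pos": n_fp,
            "mse": float(cv.mean_mse[cv.index_for(crit)]),
            "selected": sel.selected,
        }
    return out


def replicate_table1(
    settings=("high", "mixed", "low"),
    alphas=(1.0, 0.75, 0.5, 0.3, 0.1, 0.05, 0.01),
    criteria=("min", "1se"),
    n_reps: int = 100,
    p: int = 5000,
    n_causal: int = 25,
    seed: int = 0,
    k: int = 10,
    config: SolverConfig | None = None,
) -> EvaluationSummary:
    """Median/SD of correct and false-positive counts per grid cell.

    Replicate seeds derive deterministically from the master seed; a
    failed replicate is logged and excluded with its count reported in
    ``failed``.
    """
    rows = []
    failed = []
    rep_seeds = [int(s) for s in np.random.SeedSequence([int(seed), 0xEA71]).generate_state(n_reps) >> 1]
    for setting in settings:
        for alpha in alphas:
            per_crit = {c: {"correct": [], "false_pos": [], "mse": []} for c in criteria}
            for r, rs in enumerate(rep_seeds):
                try:
                    res = run_replicate(
                        setting, alpha, rs, p=p, n_causal=n_causal, k=k,
                        config=config, criteria=tuple(criteria),
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("replicate %d of (%s, %s) failed: %s", r, setting, alpha, exc)
                    failed.append((setting, alpha, r, str(exc)))
                    continue
                for c in criteria:
                    for kk in ("correct", "false_pos", "mse"):
                        per_crit[c][kk].append(res[c][kk])
            for c in criteria:
                d = per_crit[c]
                rows.append(
                    {
                        "setting": setting,
                        "alpha": alpha,
                        "criterion": c,
                        "median_correct": float(np.median(d["correct"])),
                        "sd_correct": float(np.std(d["correct"], ddof=1)) if len(d["correct"]) > 1 else 0.0,
                        "median_false_pos": float(np.median(d["false_pos"])),
                        "sd_false_pos": float(np.std(d["false_pos"], ddof=1)) if len(d["false_pos"]) > 1 else 0.0,
                        "mean_mse": float(np.mean(d["mse"])),
                        "sd_mse": float(np.std(d["mse"], ddof=1)) if len(d["mse"]) > 1 else 0.0,
                        "n_reps": len(d["correct"]),
                    }
                )
    table = pd.DataFrame(rows)
    return EvaluationSummary(table=table, n_causal=n_causal, p=p, n_reps=n_reps, failed=failed)


def overlap_counts(sets: dict[str, set]) -> dict[str, int]:
    """Cardinality of every intersection region of up to three sets.

    Keys are '&'-joined sorted name combinations for the exclusive
    regions (elements in exactly those sets), e.g. for sets A, B the keys
    are 'A', 'B' and 'A&B'.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if len(sets) > 3:
        raise ValueError("overlap regions are computed for up to three sets")
    names = sorted(sets)
    sets = {k: set(v) for k, v in sets.items()}
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out
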