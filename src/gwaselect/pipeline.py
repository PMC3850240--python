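"""Run configuration and the top-level pipeline driver.

A run is fully described by a flat ``key: value`` text config (echoed to
the log verbatim) and a master seed; every randomized stage receives a
named child seed derived from the master, so a run is reproducible from
its config alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .evaluate import replicate_table1
from .solver import SolverConfig

__all__ = ["RunConfig", "load_config", "child_seed", "run_pipeline"]

logger = logging.getLogger(__name__)


def child_seed(master: int, name: str) -> int:
    """Deterministic named sub-seed (< 2^31) of a master seed."""
    h = np.random.SeedSequence(
        [int(master), int.from_bytes(name.encode()[:8].ljust(8, b"\0"), "little") % (2**32)]
    )
    return int(h.generate_state(1)[0] >> 1)


@dataclass
class RunConfig:
    seed: int = 0
    settings: tuple[str, ...] = ("high", "mixed", "low")
    alphas: tuple[float, ...] = (1.0, 0.1)
    criteria: tuple[str, ...] = ("min", "1se")
    k: int = 10
    epsilon: float = 0.001
    K: int = 100
    reps: int = 11
    p: int = 5000
    n_causal: int = 25
    out: str = "evaluation.tsv"

    def __post_init__(self) -> None:
        for a in self.alphas:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha {a} outside [0, 1]")
        for c in self.criteria:
            if c not in ("min", "1se"):
                raise ValueError(f"unknown criterion {c!r}")
        for s in self.settings:
            if s not in ("high", "mixed", "low"):
                raise ValueError(f"unknown setting {s!r}")
        if self.k < 2 or self.reps < 1 or self.p < 10 or self.n_causal < 1:
            raise ValueError("invalid sizes in config")
        SolverConfig(epsilon=self.epsilon, K=self.K)  # validates path settings

    def solver_config(self) -> SolverConfig:
        return SolverConfig(epsilon=self.epsilon, K=self.K)


_TUPLE_FIELDS = {"settings": str, "alphas": float, "criteria": str}


def load_config(path) -> RunConfig:
    """Parse a flat ``key: value`` text config into a RunConfig."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, val = (s.strip() for s in line.split(":", 1))
        raw[key] = val
    kwargs = {}
    valid = {f.name: f.type for f in fields(RunConfig)}
    for key, val in raw.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r}")
        if key in _TUPLE_FIELDS:
            conv = _TUPLE_FIELDS[key]
            kwargs[key] = tuple(conv(v.strip()) for v in val.split(","))
        elif key in ("epsilon",):
            kwargs[key] = float(val)
        elif key == "out":
            kwargs[key] = val
        else:
            kwargs[key] = int(val)
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> int:
    """Execute the evaluation pipeline described by the config.

    Simulates replicates of each setting, fits and cross-validates every
    penalty weight, scores selections against the causal set, and writes
    the summary table.  Returns a process exit status (0 on success).
    """
    from .io import write_selection

    logger.info("run config: %s", config)
    try:
        summary = replicate_table1(
            settings=config.settings,
            alphas=config.alphas,
            criteria=config.criteria,
            n_reps=config.reps,
            p=config.p,
            n_causal=config.n_causal,
            seed=child_seed(config.seed, "table1"),
            k=config.k,
            config=config.solver_config(),
        )
    except Exception:
        logger.exception("pipeline failed")
        return 1
    write_selection(summary, config.out)
    logger.info("wrote %s (%d cells, %d failed replicates)",
                config.out, len(summary.table), len(summary.failed))
    return 0
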