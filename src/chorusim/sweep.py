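"""Factorial parameter sweep: expand the design grid, run replicated seeded
nights, and pool the per-female outcome rows into one table.

The default grid crosses 10 strategy:parameter pairs (best-of-n for n = 1..5,
minimum-threshold for θ = 6, 12, 18, 24, and random choice) with 4 male
population pulse-number means, 4 female counts (operational sex ratios
0.2–0.8 against 25 males) and 3 male spatial distributions, at 100 replicates
per cell: 48,000 runs.  The modified no-switch best-of-n variant is run as a
separate sweep over the same grid.

Each cell replicate gets a seed derived by hashing its condition labels
together with the base seed, so any single cell can be re-run in isolation
(or the whole sweep chunked/parallelised) and reproduce its rows bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run_simulation
from .strategies import Strategy
from .swamp import SpatialDistribution, Swamp

__all__ = [
    "DEFAULT_STRATEGIES",
    "SweepConfig",
    "cell_seed",
    "expand_grid",
    "run_sweep",
    "write_outcomes",
    "read_outcomes",
]

logger = logging.getLogger(__name__)

DEFAULT_STRATEGIES: tuple[Strategy, ...] = (
    *(Strategy("best_of_n", n) for n in range(1, 6)),
    *(Strategy("min_threshold", t) for t in (6, 12, 18, 24)),
    Strategy("random"),
)


@dataclass(frozen=True)
class SweepConfig:
    """The factorial design plus the engine constants shared by every cell."""

    strategies: tuple[Strategy, ...] = DEFAULT_STRATEGIES
    pop_means: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    n_females_list: tuple[int, ...] = (5, 10, 15, 20)
    distributions: tuple[SpatialDistribution, ...] = (
        SpatialDistribution.GAUSSIAN,
        SpatialDistribution.INVERSE_GAUSSIAN,
        SpatialDistribution.RANDOM,
    )
    replicates: int = 100
    base_seed: int = 0
    n_males: int = 25
    pop_sd: float = 2.0
    swamp: Swamp = field(default_factory=Swamp)
    min_spacing: float = 50.0
    speed: float = 2.0
    contact_radius: float = 5.0
    max_cycles: int = 14_400

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.strategies and self.pop_means and self.n_females_list
                and self.distributions):
            raise ValueError("every design factor needs at least one level")

    @property
    def size(self) -> int:
        return (len(self.strategies) * len(self.pop_means)
                * len(self.n_females_list) * len(self.distributions)
                * self.replicates)


def cell_seed(base_seed: int, strategy: Strategy, pop_mean: float,
              n_females: int, distribution: SpatialDistribution,
              replicate: int) -> int:
    """Stable per-replicate seed: base seed XOR a hash of the cell labels.

    Independent of enumeration order, so any cell reproduces in isolation
    and parallel chunking cannot change results.
    """
    label = (f"{strategy}|{pop_mean:g}|{n_females}"
             f"|{SpatialDistribution(distribution).value}|{replicate}")
    h = int.from_bytes(
        hashlib.blake2b(label.encode(), digest_size=8).digest(), "big")
    return (int(base_seed) ^ h) & 0x7FFF_FFFF_FFFF_FFFF


def expand_grid(sweep: SweepConfig) -> list[SimulationConfig]:
    """Deterministically enumerate every (cell, replicate) as a run config."""
    configs: list[SimulationConfig] = []
    for strat in sweep.strategies:
        for pm in sweep.pop_means:
            for nf in sweep.n_females_list:
                for dist in sweep.distributions:
                    for r in range(sweep.replicates):
                        configs.append(SimulationConfig(
                            strategy=strat,
                            n_females=nf,
                            n_males=sweep.n_males,
                            pop_mean=pm,
                            pop_sd=sweep.pop_sd,
                            distribution=dist,
                            swamp=sweep.swamp,
                            min_spacing=sweep.min_spacing,
                            speed=sweep.speed,
                            contact_radius=sweep.contact_radius,
                            max_cycles=sweep.max_cycles,
                            seed=cell_seed(sweep.base_seed, strat, pm, nf,
                                           dist, r),
                        ))
    return configs


def run_sweep(
    sweep: SweepConfig,
    configs: list[SimulationConfig] | None = None,
    log_every: int = 2000,
) -> pd.DataFrame:
    """Run every config (default: the full grid) and pool the outcome rows.

    Returns one row per female with her condition labels, mating result,
    mate pulse number (NaN when unmated), distance traveled, number of
    distinct consecutive targets and active cycles.  Pass a subset of
    ``expand_grid(sweep)`` as ``configs`` for chunked or resumed execution;
    per-cell seeding makes the pooled result independent of chunking order.
    """
    if configs is None:
        configs = expand_grid(sweep)
    cols: dict[str, list] = {k: [] for k in (
        "strategy_class", "param", "strategy", "pop_mean", "n_females",
        "distribution", "replicate", "seed", "female_id", "mated",
        "mate_pulsenumber", "distance_cm", "n_targets", "cycles")}
    t0 = time.perf_counter()
    limit_hits = 0
    rep_counter: dict[tuple, int] = {}
    for i, cfg in enumerate(configs, 1):
        try:
            res = run_simulation(cfg)
        except Exception:
            logger.error("run failed for %s (seed %d)", cfg.strategy, cfg.seed)
            raise
        limit_hits += res.hit_time_limit
        key = (str(cfg.strategy), cfg.pop_mean, cfg.n_females,
               cfg.distribution.value)
        rep = rep_counter.get(key, 0)
        rep_counter[key] = rep + 1
        param = np.nan if cfg.strategy.param is None else float(cfg.strategy.param)
        for o in res.outcomes:
            cols["strategy_class"].append(cfg.strategy.strategy_class)
            cols["param"].append(param)
            cols["strategy"].append(str(cfg.strategy))
            cols["pop_mean"].append(cfg.pop_mean)
            cols["n_females"].append(cfg.n_females)
            cols["distribution"].append(cfg.distribution.value)
            cols["replicate"].append(rep)
            cols["seed"].append(cfg.seed)
            cols["female_id"].append(o.female_id)
            cols["mated"].append(o.mated)
            cols["mate_pulsenumber"].append(
                np.nan if o.mate_pulsenumber is None else o.mate_pulsenumber)
            cols["distance_cm"].append(o.distance_cm)
            cols["n_targets"].append(o.n_targets)
            cols["cycles"].append(o.cycles_active)
        if log_every and i % log_every == 0:
            logger.info("sweep progress: %d/%d runs (%.1fs elapsed)",
                        i, len(configs), time.perf_counter() - t0)
    if limit_hits:
        logger.warning("%d runs hit the cycle limit", limit_hits)
    df = pd.DataFrame(cols)
    df["mate_pulsenumber"] = df["mate_pulsenumber"].astype("float64")
    df["param"] = df["param"].astype("float64")
    return df


def write_outcomes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    return pd.read_csv(path)
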