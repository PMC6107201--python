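"""Single-night chorus simulation.

One run simulates a single evening of mating activity in 1-second cycles.
Each cycle has three synchronous phases:

1. *Retarget* — every searching female (re)selects a target according to her
   strategy's re-assessment rule.  Per-cycle re-assessment applies only to the
   plain best-of-n rule, and a standing target is dropped only for a strictly
   better male, so a mid-course switch always trades up; the no-switch
   variant, the threshold rule and random choice re-assess only when the
   current target is removed by mating.  A threshold female with no
   acceptable male takes one random-walk step and leaves the arena unmated.
2. *Move* — searching females approach their target in a straight line at a
   fixed speed, never overshooting.
3. *Mate* — a female who ends her move within the contact radius of her
   target mates with him; if several females reach the same male on the same
   cycle, the nearest wins (random tie-break) and the others re-assess next
   cycle.  Mated pairs leave the pool and are not replaced.

Males never move and call all night; their pulse numbers are fixed.  The run
ends when no female is still searching (a hard cycle cap exists but is
deliberately generous: under default parameters no run comes near it).

All randomness flows from a single seeded generator in a fixed draw order
(male positions, pulse numbers, female positions, then the in-run pools), so
a config with the same seed reproduces bit-identical outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .strategies import Strategy
from .swamp import (
    SpatialDistribution,
    Swamp,
    sample_female_positions,
    sample_male_positions,
    sample_pulsenumbers,
)

__all__ = [
    "SimulationConfig",
    "FemaleOutcome",
    "TargetChange",
    "SimulationResult",
    "move_toward",
    "run_simulation",
    "outcomes_to_frame",
]

_KIND_CODE = {
    "best_of_n": _kernel.KIND_BEST_OF_N,
    "best_of_n_no_switch": _kernel.KIND_BEST_OF_N_NO_SWITCH,
    "min_threshold": _kernel.KIND_MIN_THRESHOLD,
    "random": _kernel.KIND_RANDOM,
}

_REASONS = ("init", "target_mated", "better_male")


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of one night's run.

    ``speed`` (cm/cycle) and ``contact_radius`` (cm) are the movement
    constants: 2 cm/s walking speed and a one-body-length mating contact
    distance.  ``min_spacing`` is the male territory diameter.  ``max_cycles``
    caps the night at 4 h of 1-s cycles.
    """

    strategy: Strategy
    n_females: int = 10
    n_males: int = 25
    pop_mean: float = 12.0
    pop_sd: float = 2.0
    distribution: SpatialDistribution = SpatialDistribution.RANDOM
    swamp: Swamp = field(default_factory=Swamp)
    min_spacing: float = 50.0
    speed: float = 2.0
    contact_radius: float = 5.0
    max_cycles: int = 14_400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("need at least one female and one male")
        if self.speed <= 0 or self.contact_radius < 0:
            raise ValueError("speed must be > 0 and contact_radius >= 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        object.__setattr__(self, "distribution",
                           SpatialDistribution(self.distribution))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class FemaleOutcome:
    """Per-female record of how the night ended."""

    female_id: int
    mated: bool
    mate_pulsenumber: int | None
    distance_cm: float
    n_targets: int
    cycles_active: int


@dataclass(frozen=True)
class TargetChange:
    """One retargeting event; ``reason`` is 'init' (first target),
    'target_mated' (old target left with another female) or 'better_male'
    (best-of-n trade-up while the old target was still available)."""

    cycle: int
    female_id: int
    old_target: int | None
    new_target: int
    old_pulsenumber: int | None
    new_pulsenumber: int
    reason: str


@dataclass
class SimulationResult:
    """Outcomes plus run metadata; iterates over the per-female outcomes."""

    config: SimulationConfig
    outcomes: list[FemaleOutcome]
    cycles: int
    hit_time_limit: bool
    male_positions: np.ndarray
    male_pulsenumbers: np.ndarray
    female_start_positions: np.ndarray
    events: list[TargetChange] | None = None

    def __iter__(self):
        return iter(self.outcomes)

    def __len__(self) -> int:
        return len(self.outcomes)


def move_toward(current: np.ndarray, target: np.ndarray,
                speed: float) -> tuple[np.ndarray, float]:
    """Advance ``current`` straight toward ``target`` by at most ``speed`` cm,
    stopping exactly at the target if it is nearer than one step.  Returns the
    new position and the distance actually covered."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    current = np.asarray(current, dtype=float)
    vec = np.asarray(target, dtype=float) - current
    d = float(np.hypot(*vec))
    if d <= speed:
        return np.asarray(target, dtype=float).copy(), d
    return current + vec * (speed / d), speed


def run_simulation(config: SimulationConfig,
                   record_events: bool = False) -> SimulationResult:
    """Run one night and return per-female outcomes.

    ``record_events`` additionally logs every retargeting event (used for
    auditing the re-assessment rules; off by default for speed).
    """
    rng = np.random.default_rng(config.seed)
    male_pos = sample_male_positions(
        config.distribution, config.n_males, config.min_spacing,
        config.swamp, rng,
    )
    pulse = sample_pulsenumbers(
        config.pop_mean, config.pop_sd, config.n_males, rng)
    f_start = sample_female_positions(config.n_females, config.swamp, rng)

    F = config.n_females
    # In-run randomness, pre-drawn in a fixed order: one walk angle per
    # female, tie-break uniforms, and (random strategy only) target-choice
    # uniforms sized for the worst-case number of retargets.
    walk_angles = rng.uniform(0.0, 2.0 * np.pi, size=F)
    tie_pool = rng.random(4 * F + 4)
    if config.strategy.kind == "random":
        choice_pool = rng.random(F * (F + 3))
    else:
        choice_pool = np.empty(1)

    kind = _KIND_CODE[config.strategy.kind]
    param = config.strategy.param or 0
    # bounded: trade-ups strictly increase pulse number, other changes are
    # capped by the number of matings
    ev_cap = F * (int(pulse.max()) + F + 4) if record_events else 1
    ev_buf = np.zeros((ev_cap, _kernel.EVENT_COLS), dtype=np.int64)

    fx = np.ascontiguousarray(f_start[:, 0].copy())
    fy = np.ascontiguousarray(f_start[:, 1].copy())
    (status, mate_pn, dist, n_targets, cycles_active, cycles, hit_limit,
     n_events) = _kernel.simulate_night(
        np.ascontiguousarray(male_pos[:, 0]),
        np.ascontiguousarray(male_pos[:, 1]),
        pulse, fx, fy,
        kind, param,
        float(config.speed), float(config.contact_radius),
        float(config.swamp.width), float(config.swamp.depth),
        int(config.max_cycles),
        walk_angles, choice_pool, tie_pool,
        bool(record_events), ev_buf,
    )

    outcomes = [
        FemaleOutcome(
            female_id=i,
            mated=status[i] == _kernel.MATED,
            mate_pulsenumber=(int(mate_pn[i])
                              if status[i] == _kernel.MATED else None),
            distance_cm=float(dist[i]),
            n_targets=int(n_targets[i]),
            cycles_active=int(cycles_active[i]),
        )
        for i in range(F)
    ]
    events = None
    if record_events:
        events = [
            TargetChange(
                cycle=int(r[0]), female_id=int(r[1]),
                old_target=None if r[2] < 0 else int(r[2]),
                new_target=int(r[3]),
                old_pulsenumber=None if r[2] < 0 else int(r[4]),
                new_pulsenumber=int(r[5]),
                reason=_REASONS[int(r[6])],
            )
            for r in ev_buf[:n_events]
        ]
    return SimulationResult(
        config=config,
        outcomes=outcomes,
        cycles=int(cycles),
        hit_time_limit=bool(hit_limit),
        male_positions=male_pos,
        male_pulsenumbers=pulse,
        female_start_positions=f_start,
        events=events,
    )


def outcomes_to_frame(result: SimulationResult) -> pd.DataFrame:
    """One tidy row per female, with the run's condition labels attached."""
    cfg = result.config
    rows = pd.DataFrame([o.__dict__ for o in result.outcomes])
    rows["mate_pulsenumber"] = rows["mate_pulsenumber"].astype("float64")
    rows.insert(0, "strategy_class", cfg.strategy.strategy_class)
    rows.insert(1, "param", np.nan if cfg.strategy.param is None
                else float(cfg.strategy.param))
    rows.insert(2, "strategy", str(cfg.strategy))
    rows.insert(3, "pop_mean", cfg.pop_mean)
    rows.insert(4, "n_females", cfg.n_females)
    rows.insert(5, "distribution", cfg.distribution.value)
    rows.insert(6, "seed", cfg.seed)
    return rows
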