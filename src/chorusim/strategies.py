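"""Female target-selection rules.

Three classic decision rules are implemented, all operating on the set of
currently available (unmated) males, which every female is assumed to hear
from anywhere in the arena:

* ``best_of_n`` — assess the ``n`` spatially closest males and target the one
  with the highest pulse number.  Females re-assess every time step as they
  move; a standing target is abandoned only for a strictly better male (or
  when the target mates), so a switch never lowers target quality.
* ``best_of_n_no_switch`` — same selection rule, but a female re-assesses only
  when her current target is removed by mating.
* ``min_threshold`` — sequential-search rule: target the closest male whose
  pulse number is at least the internal threshold θ; keep him unless he mates.
  If no male meets θ the rule returns no target, and the caller removes the
  female from the night's pool.
* ``random`` — target a uniformly random available male anywhere in the
  arena; keep him unless he mates.

Functions here are scalar (one female at a time) and are the reference
semantics; the simulation engine vectorises the per-cycle ``best_of_n`` path
but must agree with these functions choice-for-choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STRATEGY_KINDS",
    "Strategy",
    "closest_males",
    "choose_target_best_of_n",
    "choose_target_min_threshold",
    "choose_target_random",
]

STRATEGY_KINDS = ("best_of_n", "best_of_n_no_switch", "min_threshold", "random")

#: kinds whose parameter is the sample size n
_N_KINDS = ("best_of_n", "best_of_n_no_switch")


@dataclass(frozen=True)
class Strategy:
    """A strategy kind plus its parameter (n for best-of-n kinds, θ for the
    threshold rule, nothing for random choice)."""

    kind: str
    param: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "random":
            if self.param is not None:
                raise ValueError("random strategy takes no parameter")
        else:
            if self.param is None or self.param < 1:
                raise ValueError(f"{self.kind} needs a positive integer parameter")

    @property
    def strategy_class(self) -> str:
        """Class label used for pooled reporting (parameter stripped)."""
        return self.kind

    @classmethod
    def from_string(cls, text: str) -> "Strategy":
        """Parse config strings like ``best_of_n:3`` or ``random``."""
        kind, sep, param = text.partition(":")
        kind = kind.strip()
        if not sep:
            return cls(kind, None)
        return cls(kind, int(param))

    def __str__(self) -> str:
        return self.kind if self.param is None else f"{self.kind}:{self.param}"


def closest_males(
    female_pos: np.ndarray,
    male_pos: np.ndarray,
    alive: np.ndarray,
    k: int,
) -> np.ndarray:
    """Ids of the up-to-``k`` closest available males, by ascending Euclidean
    distance; equal distances break toward the lower id.  Returns an empty
    array when no male is available."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = np.square(male_pos - np.asarray(female_pos)).sum(axis=1)
    d2 = np.where(alive, d2, np.inf)
    order = np.argsort(d2, kind="stable")
    n_alive = int(np.count_nonzero(alive))
    return order[: min(k, n_alive)]


def choose_target_best_of_n(
    female_pos: np.ndarray,
    male_pos: np.ndarray,
    alive: np.ndarray,
    pulsenumbers: np.ndarray,
    n: int,
    current: int | None = None,
) -> int | None:
    """Best-of-n choice: highest pulse number among the n closest available
    males; pulse-number ties break toward the closer male, then the lower id.

    When ``current`` is a still-available male, he is retained unless the
    candidate is *strictly* better, so re-assessment while travelling can only
    trade up.  Returns ``None`` when no male is available.
    """
    ids = closest_males(female_pos, male_pos, alive, n)
    if ids.size == 0:
        return None
    # ids are distance-ordered, so argmax (first occurrence) applies the
    # closer-then-lower-id tie break for free.
    cand = int(ids[int(np.argmax(pulsenumbers[ids]))])
    if current is not None and alive[current] and \
            pulsenumbers[cand] <= pulsenumbers[current]:
        return int(current)
    return cand


def choose_target_min_threshold(
    female_pos: np.ndarray,
    male_pos: np.ndarray,
    alive: np.ndarray,
    pulsenumbers: np.ndarray,
    theta: int,
) -> int | None:
    """Closest available male whose pulse number is at least ``theta``;
    ``None`` when no such male exists (the caller then removes the female —
    she can hear every male, so no acceptable male now means none ever)."""
    ok = alive & (pulsenumbers >= theta)
    if not ok.any():
        return None
    d2 = np.square(male_pos - np.asarray(female_pos)).sum(axis=1)
    d2 = np.where(ok, d2, np.inf)
    return int(np.argmin(d2))  # first occurrence => lower id on exact ties


def choose_target_random(
    alive: np.ndarray,
    rng: np.random.Generator,
) -> int | None:
    """Uniform draw over available males; ``None`` if none remain."""
    ids = np.flatnonzero(alive)
    if ids.size == 0:
        return None
    return int(rng.choice(ids))
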