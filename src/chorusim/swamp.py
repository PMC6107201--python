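"""Chorus arena geometry and initial agent placement.

The simulated environment is a rectangular wetland ("swamp") of 10 x 25 m
(1000 x 2500 cm) with hard boundaries.  Calling males hold fixed territories
inside the arena and advertise with a call whose *pulse number* (pulses per
call) is the quality cue females rank; females enter the arena on its
perimeter and approach males by phonotaxis.  This module builds that initial
configuration: male territory positions under three spatial regimes, integer
pulse numbers drawn around a population mean, and female start positions
uniform along the perimeter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Swamp",
    "SpatialDistribution",
    "PlacementError",
    "sample_male_positions",
    "sample_pulsenumbers",
    "sample_female_positions",
    "placement_table",
]


class PlacementError(RuntimeError):
    """Raised when the requested male packing cannot be realised."""


@dataclass(frozen=True)
class Swamp:
    """Rectangular arena, in cm.  Coordinates live in [0, width] x [0, depth].

    ``width`` is the short (x) extent, ``depth`` the long (y) extent; defaults
    give the 10 x 25 m wetland.  Boundaries are hard walls: nothing wraps and
    no agent ever leaves the rectangle.
    """

    width: float = 1000.0
    depth: float = 2500.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("swamp dimensions must be positive")

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.depth)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= self.depth)
        )

    def clip(self, xy: np.ndarray) -> np.ndarray:
        return np.clip(xy, [0.0, 0.0], [self.width, self.depth])


class SpatialDistribution(str, Enum):
    """Male placement regime: centre-peaked, edge-peaked or uniform."""

    GAUSSIAN = "gaussian"
    INVERSE_GAUSSIAN = "inverse_gaussian"
    RANDOM = "random"


def _truncated_normal(center: float, sigma: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    # Rejection is cheap here: with sigma = extent / 6 about 99.7% of draws
    # land inside before truncation.
    for _ in range(10_000):
        u = rng.normal(center, sigma)
        if lo <= u <= hi:
            return u
    raise PlacementError("truncated-normal rejection budget exhausted")


def _candidate(kind: SpatialDistribution, swamp: Swamp,
               rng: np.random.Generator) -> np.ndarray:
    if kind == SpatialDistribution.RANDOM:
        return rng.uniform([0.0, 0.0], [swamp.width, swamp.depth])
    coords = []
    for extent in (swamp.width, swamp.depth):
        u = _truncated_normal(extent / 2.0, extent / 6.0, 0.0, extent, rng)
        if kind == SpatialDistribution.INVERSE_GAUSSIAN:
            # Shift the centre-peaked draw by half the extent (mod extent) so
            # the density peaks at both edges instead of the middle, matching
            # shoreline-style aggregations.
            u = (u + extent / 2.0) % extent
        coords.append(u)
    return np.asarray(coords)


def sample_male_positions(
    kind: SpatialDistribution | str,
    n_males: int,
    min_spacing: float,
    swamp: Swamp,
    rng: np.random.Generator,
    max_rejections: int = 10_000,
) -> np.ndarray:
    """Place ``n_males`` territory centres, pairwise at least ``min_spacing``
    cm apart (territories of >= ``min_spacing`` diameter).

    Males are placed sequentially; a candidate violating the spacing against
    any already-placed male is redrawn.  Raises :class:`PlacementError` after
    ``max_rejections`` failed candidates for a single male, which in practice
    flags an infeasible packing.

    Returns an ``(n_males, 2)`` float array of positions in cm.
    """
    kind = SpatialDistribution(kind)
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    placed = np.empty((n_males, 2))
    sq = min_spacing * min_spacing
    for i in range(n_males):
        for _ in range(max_rejections):
            cand = _candidate(kind, swamp, rng)
            if i == 0:
                placed[0] = cand
                break
            d2 = np.square(placed[:i] - cand).sum(axis=1)
            if (d2 >= sq).all():
                placed[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place male {i} of {n_males} with spacing "
                f"{min_spacing} cm after {max_rejections} rejections"
            )
    return placed


def sample_pulsenumbers(
    pop_mean: float,
    pop_sd: float,
    n_males: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw integer call pulse numbers for ``n_males`` males.

    Draws are Normal(``pop_mean``, ``pop_sd``), rounded to the nearest
    integer and clamped to >= 1: pulse counts are integers and a calling male
    produces at least one pulse.  Each male's pulse number is fixed for the
    whole night.
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    if not pop_sd > 0:
        raise ValueError("pop_sd must be > 0")
    if not pop_mean > 0:
        raise ValueError("pop_mean must be > 0")
    draws = rng.normal(pop_mean, pop_sd, size=n_males)
    return np.maximum(1, np.rint(draws)).astype(np.int64)


def sample_female_positions(
    n_females: int,
    swamp: Swamp,
    rng: np.random.Generator,
    edges: str = "long",
) -> np.ndarray:
    """Place arriving females on the arena boundary.

    With ``edges="long"`` (default) each female lands uniformly on one of
    the two long edges — the shorelines of the elongated wetland, where
    females enter the chorus.  ``edges="perimeter"`` instead samples arc
    length uniformly along the whole boundary, so every edge receives
    points in proportion to its length.  Returns an ``(n_females, 2)``
    array.
    """
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    w, d = swamp.width, swamp.depth
    pos = np.empty((n_females, 2))
    if edges == "long":
        side = rng.integers(0, 2, size=n_females)
        pos[:, 0] = side * w
        pos[:, 1] = rng.uniform(0.0, d, size=n_females)
        return pos
    if edges != "perimeter":
        raise ValueError("edges must be 'long' or 'perimeter'")
    s = rng.uniform(0.0, swamp.perimeter, size=n_females)
    for i, t in enumerate(s):
        if t < w:                      # bottom edge, y = 0
            pos[i] = (t, 0.0)
        elif t < w + d:                # right edge, x = width
            pos[i] = (w, t - w)
        elif t < 2 * w + d:            # top edge, y = depth
            pos[i] = (2 * w + d - t, d)
        else:                          # left edge, x = 0
            pos[i] = (0.0, swamp.perimeter - t)
    return pos


def placement_table(positions: np.ndarray,
                    pulsenumbers: np.ndarray | None = None) -> pd.DataFrame:
    """Snapshot of a placement as a tidy table (id, x_cm, y_cm[, pulsenumber]),
    convenient for writing delimited text and plotting arena maps."""
    out = pd.DataFrame(
        {
            "id": np.arange(len(positions)),
            "x_cm": positions[:, 0],
            "y_cm": positions[:, 1],
        }
    )
    if pulsenumbers is not None:
        out["pulsenumber"] = np.asarray(pulsenumbers)
    return out
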