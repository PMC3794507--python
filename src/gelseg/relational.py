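"""Fuzzy-relational spot refinement.

After intensity clustering, a fuzzy relation is set up between pixels
of *different* clusters: the relation value is the absolute gray-value
difference, compared against a linguistic threshold beta through
trapezoidal "high"/"low" membership functions.  If the difference is
High, the pixel with the higher gray value is a spot pixel; if the
difference is Low and exactly one of the two is already a spot pixel,
the other becomes one too (iterated to a fixed point).

Because the relation depends only on (gray value, cluster), pixel pairs
collapse exactly onto gray-level pairs: at most 256x256 comparisons
instead of N^2 pixel pairs, with identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fcm import FcmResult, hard_labels

logger = logging.getLogger("gelseg")


def approx_equal_membership(u: int, v: int) -> float:
    """The worked 'approximately equal' relation on the universe {1,2,3}:
    1 on the diagonal, 0.8 at |u-v| = 1, 0.3 at |u-v| = 2."""
    if u not in (1, 2, 3) or v not in (1, 2, 3):
        raise ValueError("arguments must lie in the universe {1, 2, 3}")
    return {0: 1.0, 1: 0.8, 2: 0.3}[abs(u - v)]


def trapezoid_membership(x, pts) -> np.ndarray | float:
    """Trapezoidal membership max(min((x-a)/(b-a), 1, (d-x)/(d-c)), 0).

    Breakpoints must satisfy a <= b <= c <= d; a degenerate edge (b = a
    or d = c) acts as a step.  Accepts scalars or arrays.
    """
    a, b, c, d = pts
    if not (a <= b <= c <= d):
        raise ValueError(f"breakpoints must be ordered, got {pts}")
    x = np.asarray(x, dtype=np.float64)
    rise = np.where(x >= b, 1.0, (x - a) / (b - a) if b > a else np.where(x >= a, 1.0, 0.0))
    fall = np.where(x <= c, 1.0, (d - x) / (d - c) if d > c else np.where(x <= d, 1.0, 0.0))
    out = np.maximum(np.minimum(np.minimum(rise, fall), 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TrapezoidParams:
    """Breakpoints of the 'low' and 'high' trapezoids on the gray-level
    difference axis.  The high plateau's right edge sits above 255, so
    every admissible difference beyond the ramp is fully High."""

    low_points: tuple[float, float, float, float]
    high_points: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for pts in (self.low_points, self.high_points):
            if not (pts[0] <= pts[1] <= pts[2] <= pts[3]):
                raise ValueError(f"breakpoints must be ordered, got {pts}")


@dataclass(frozen=True)
class BetaParams:
    """The fuzzy closeness threshold beta with transition half-width delta.

    ``high`` ramps from 0 at beta-delta to 1 at beta+delta, so the
    0.5-cut decision is exactly ``difference >= beta`` (the crisp rule
    recovered at delta = 0).  ``low`` is the mirror image: fully low at
    or below beta-delta.
    """

    beta: float = 19.0
    delta: float = 3.0

    def __post_init__(self) -> None:
        if self.beta - self.delta < 0 or self.beta + self.delta > 255:
            raise ValueError("require 0 <= beta-delta and beta+delta <= 255")

    @property
    def trapezoid(self) -> TrapezoidParams:
        return TrapezoidParams(
            low_points=(-2.0, -1.0, self.beta - self.delta, self.beta + self.delta),
            high_points=(self.beta - self.delta, self.beta + self.delta, 256.0, 257.0),
        )

    def high(self, k) -> np.ndarray | float:
        return trapezoid_membership(k, self.trapezoid.high_points)

    def low(self, k) -> np.ndarray | float:
        return trapezoid_membership(k, self.trapezoid.low_points)

    def to_json(self) -> str:
        import json
        return json.dumps({"beta": self.beta, "delta": self.delta})


def relation_degree(g1: int, g2: int) -> int:
    """The pixel-pair relation value: absolute gray-value difference."""
    if not (0 <= g1 <= 255 and 0 <= g2 <= 255):
        raise ValueError("gray levels must lie in [0, 255]")
    return abs(int(g1) - int(g2))


@dataclass
class LevelClusterTable:
    """Gray levels present in an image with their pixel counts and hard
    cluster assignments; the exact compression of the pixel-pair
    relation (which depends only on gray value and cluster)."""

    levels: np.ndarray
    counts: np.ndarray
    clusters: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.counts) == len(self.clusters)):
            raise ValueError("levels, counts and clusters must align")
        if len(self.levels) == 0:
            raise ValueError("empty table")


def build_level_table(img: np.ndarray, centers: np.ndarray) -> LevelClusterTable:
    """Tabulate present gray levels and assign each to its cluster
    (argmax membership, ties toward the larger center)."""
    levels, counts = np.unique(np.asarray(img).ravel(), return_counts=True)
    return LevelClusterTable(levels=levels.astype(np.int64), counts=counts,
                             clusters=hard_labels(levels, centers))


def classify_spot_levels(table: LevelClusterTable, beta: BetaParams,
                         premarked: set[int] | None = None,
                         propagate: bool = True) -> set[int]:
    """Mark spot gray levels from cross-cluster level pairs.

    Stage 1: for every pair of levels in different clusters whose
    difference is High (membership >= 0.5), the larger level is a spot
    level.  Stage 2: repeatedly, a Low cross-cluster pair with exactly
    one marked level marks the other, until a fixed point (the marked
    set grows monotonically, so at most 256 sweeps).
    """
    L = table.levels.astype(np.int64)
    K = np.asarray(table.clusters)
    if len(np.unique(K)) < 2:
        raise ValueError("relation is defined across clusters; need >= 2")
    diff = np.abs(L[:, None] - L[None, :])
    cross = K[:, None] != K[None, :]
    high = np.asarray(beta.high(diff)) >= 0.5
    marked = (cross & high & (L[:, None] > L[None, :])).any(axis=1)
    if premarked:
        marked |= np.isin(L, sorted(premarked))
    if not propagate:
        return set(int(v) for v in L[marked])
    low_adj = cross & (np.asarray(beta.low(diff)) >= 0.5)
    while True:
        newly = ~marked & (low_adj & marked[None, :]).any(axis=1)
        if not newly.any():
            break
        marked |= newly
    return set(int(v) for v in L[marked])


def relational_refine(img: np.ndarray, fcm: FcmResult | np.ndarray,
                      beta: BetaParams) -> np.ndarray:
    """Refine an FCM clustering of ``img`` into a binary spot mask.

    ``fcm`` is a fitted :class:`~gelseg.fcm.FcmResult` (or a bare center
    array).  Exactly equivalent to classifying all pixel pairs, because
    the relation depends only on gray value and cluster label.  If the
    present levels fall into a single cluster the mask is empty (warned).
    """
    img = np.asarray(img)
    centers = fcm.centers if isinstance(fcm, FcmResult) else np.asarray(fcm)
    table = build_level_table(img, centers)
    if len(np.unique(table.clusters)) < 2:
        logger.warning("single populated cluster: empty spot mask")
        return np.zeros(img.shape, dtype=np.uint8)
    marked = classify_spot_levels(table, beta)
    return np.isin(img, sorted(marked)).astype(np.uint8)
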