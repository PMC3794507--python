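"""Synthetic 2D-gel image generator with ground truth.

Emulates the look of scanned protein gels: a smooth, spatially varying
light background carrying dark, roughly Gaussian spots — including
faint "ghost" spots barely above the noise — plus additive Gaussian
noise.  Each generated gel comes with an analytic ground-truth mask
(the half-maximum disk of every spot) and a spot catalog, so detection
metrics are well defined.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

# radius of the half-maximum contour of a Gaussian dip, in sigmas
HALF_MAX_RADIUS = math.sqrt(2.0 * math.log(2.0))


class GenerationError(RuntimeError):
    """Raised when spot placement cannot satisfy the spacing constraint."""


@dataclass(frozen=True)
class SpotRecord:
    """One seeded spot: integer center, dip amplitude (gray levels),
    Gaussian radius sigma (pixels) and whether it is a ghost spot."""

    row: int
    col: int
    amplitude: float
    sigma: float
    is_ghost: bool


@dataclass(frozen=True)
class SyntheticGelSpec:
    """Parametric description of a synthetic gel.

    Defaults model an 8-bit scan: light background near 200 with a
    smooth +/- 20 gray-level tilt, strong spots dipping 80-150 levels,
    ghost spots 10-30 levels, spot radii 2.5-5 px, Gaussian noise.
    """

    height: int = 256
    width: int = 256
    n_spots: int = 30
    n_ghost: int = 10
    amp_strong: tuple[float, float] = (80.0, 150.0)
    amp_ghost: tuple[float, float] = (10.0, 30.0)
    sigma_spot: tuple[float, float] = (2.5, 5.0)
    background_base: float = 200.0
    background_tilt: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("image must be at least 2x2")
        if self.background_base - max(self.amp_strong[1], self.amp_ghost[1]) < 0:
            raise ValueError("maximum dip must not undershoot 0 before clipping")
        for lo, hi in (self.amp_strong, self.amp_ghost, self.sigma_spot):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.n_spots < 0 or self.n_ghost < 0 or self.noise_sd < 0:
            raise ValueError("counts and noise_sd must be non-negative")


def _background(spec: SyntheticGelSpec, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    X = 2.0 * xx / max(spec.width - 1, 1) - 1.0
    Y = 2.0 * yy / max(spec.height - 1, 1) - 1.0
    c = rng.uniform(-1.0, 1.0, size=5)
    f = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * X**2 + c[4] * Y**2
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return spec.background_base + spec.background_tilt * f


def _place_spots(spec: SyntheticGelSpec, rng: np.random.Generator) -> list[SpotRecord]:
    plan = [(spec.amp_strong, False)] * spec.n_spots + [(spec.amp_ghost, True)] * spec.n_ghost
    spots: list[SpotRecord] = []
    max_tries = 1000
    for (amp_lo, amp_hi), ghost in plan:
        # sigma is redrawn per attempt so crowded layouts can fall back
        # to smaller spots instead of failing outright
        for _ in range(max_tries):
            sigma = float(rng.uniform(*spec.sigma_spot))
            amp = float(rng.uniform(amp_lo, amp_hi))
            margin = int(math.ceil(3 * sigma))
            if spec.height - 1 - margin <= margin or spec.width - 1 - margin <= margin:
                continue
            r = int(rng.integers(margin, spec.height - margin))
            c = int(rng.integers(margin, spec.width - margin))
            # 2(sigma_i + sigma_j) spacing keeps half-maximum disks disjoint
            if all(math.hypot(r - s.row, c - s.col) >= 2.0 * (sigma + s.sigma)
                   for s in spots):
                spots.append(SpotRecord(r, c, amp, sigma, ghost))
                break
        else:
            raise GenerationError(
                f"could not place spot {len(spots) + 1} after {max_tries} tries")
    return spots


def spot_truth_disk(spot: SpotRecord, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the spot's analytic half-maximum disk (pixels
    where the spot's own dip is at least half its amplitude)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r2 = (yy - spot.row) ** 2 + (xx - spot.col) ** 2
    return r2 <= (HALF_MAX_RADIUS * spot.sigma) ** 2


def generate_gel(spec: SyntheticGelSpec) -> tuple[np.ndarray, np.ndarray, list[SpotRecord]]:
    """Render a gel image, its ground-truth spot mask and spot catalog.

    image = clip(round(background - sum of Gaussian dips + noise)).
    Noise is drawn last, so regenerating with ``noise_sd = 0`` and the
    same seed yields the clean counterpart of a noisy gel.
    """
    rng = np.random.default_rng(spec.seed)
    bg = _background(spec, rng)
    spots = _place_spots(spec, rng)
    dips = np.zeros((spec.height, spec.width))
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    for s in spots:
        r2 = (yy - s.row) ** 2 + (xx - s.col) ** 2
        dips += s.amplitude * np.exp(-r2 / (2.0 * s.sigma**2))
        mask[r2 <= (HALF_MAX_RADIUS * s.sigma) ** 2] = 1
    img = bg - dips
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask, spots


def clean_counterpart(spec: SyntheticGelSpec) -> np.ndarray:
    """The noise-free image of the same gel (same seed, noise_sd = 0)."""
    img, _, _ = generate_gel(replace(spec, noise_sd=0.0))
    return img


def write_catalog(spots: list[SpotRecord], path: str | Path) -> None:
    """Write the spot catalog as CSV (x, y, amplitude, sigma, is_ghost)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "amplitude", "sigma", "is_ghost"])
        for s in spots:
            w.writerow([s.col, s.row, s.amplitude, s.sigma, int(s.is_ghost)])


@dataclass(frozen=True)
class GelSample:
    """One benchmark gel: image, truth mask, catalog and its spec."""

    image: np.ndarray
    truth: np.ndarray
    catalog: tuple[SpotRecord, ...]
    spec: SyntheticGelSpec


# noise level and ghost fraction per benchmark gel; total 40 spots each.
_BENCHMARK_CONDITIONS = (
    (2.0, 0.2), (2.0, 0.5), (5.0, 0.2), (5.0, 0.5),
    (10.0, 0.2), (10.0, 0.5), (5.0, 0.25),
)
_BENCHMARK_TOTAL_SPOTS = 40


def default_benchmark_suite(seed: int = 0) -> list[GelSample]:
    """Seven seeded 256x256 gels spanning noise levels 2/5/10 and ghost
    fractions 0.2/0.5 (plus a 30-strong + 10-ghost middle condition)."""
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(_BENCHMARK_CONDITIONS)) % (2**31)
    suite = []
    for (noise_sd, ghost_frac), s in zip(_BENCHMARK_CONDITIONS, child_seeds):
        n_ghost = round(_BENCHMARK_TOTAL_SPOTS * ghost_frac)
        spec = SyntheticGelSpec(
            n_spots=_BENCHMARK_TOTAL_SPOTS - n_ghost, n_ghost=n_ghost,
            noise_sd=noise_sd, seed=int(s))
        img, mask, spots = generate_gel(spec)
        suite.append(GelSample(image=img, truth=mask,
                               catalog=tuple(spots), spec=spec))
    return suite
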