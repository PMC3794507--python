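"""Raster I/O and run configuration.

Gel scans are single-channel 8-bit rasters.  Everything downstream
(wavelet sharpening, intensity clustering, relational refinement)
operates on plain 2-D ``numpy.uint8`` arrays with even dimensions; this
module is the boundary where files, bit depths, colour channels and odd
sizes are normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("gelseg")

POLARITIES = ("spots_dark", "spots_bright")


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster plus the padding applied to even its size.

    ``pixels`` always has even height and width; ``pad_bottom`` /
    ``pad_right`` record how many replicated rows/columns were appended
    so that results can be cropped back to the original footprint.
    """

    pixels: np.ndarray
    pad_bottom: int = 0
    pad_right: int = 0

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image too small: {px.shape}")
        if px.shape[0] % 2 or px.shape[1] % 2:
            raise ValueError(f"dimensions must be even, got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def crop(self, arr: np.ndarray | None = None) -> np.ndarray:
        """Return ``arr`` (default: the pixels) cropped to the original,
        pre-padding footprint."""
        if arr is None:
            arr = self.pixels
        h = arr.shape[0] - self.pad_bottom
        w = arr.shape[1] - self.pad_right
        return arr[:h, :w]


def ensure_even(arr: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Symmetrically pad a 2-D array so both dimensions are even.

    Returns ``(padded, pad_bottom, pad_right)``.  Padding replicates the
    edge row/column (symmetric extension), so crop-back is the identity
    on the original region.
    """
    pb = arr.shape[0] % 2
    pr = arr.shape[1] % 2
    if pb or pr:
        arr = np.pad(arr, ((0, pb), (0, pr)), mode="symmetric")
    return arr, pb, pr


def _to_uint8(raw: np.ndarray) -> np.ndarray:
    if raw.ndim == 3:
        # multi-channel: luminance by plain channel average (alpha dropped)
        rgb = raw[..., :3] if raw.shape[-1] == 4 else raw
        raw = rgb.astype(np.float64).mean(axis=-1)
    if raw.dtype == np.uint16:
        logger.warning("16-bit input rescaled to 8-bit range")
        raw = raw.astype(np.float64) / 257.0
    return np.clip(np.rint(np.asarray(raw, dtype=np.float64)), 0, 255).astype(np.uint8)


def load_gray_image(path: str | Path) -> GrayImage:
    """Read a raster image as 8-bit grayscale.

    Multi-channel inputs are converted by averaging the colour channels;
    16-bit inputs are linearly rescaled; odd dimensions are symmetrically
    padded to even and the pad recorded for later cropping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ValueError(f"unreadable image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"empty image {path}")
    gray = _to_uint8(raw)
    if gray.ndim != 2 or min(gray.shape) < 2:
        raise ValueError(f"not a 2-D raster of usable size: shape {gray.shape}")
    gray, pb, pr = ensure_even(gray)
    return GrayImage(gray, pad_bottom=pb, pad_right=pr)


def save_gray_image(img: np.ndarray | GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (crops recorded padding first)."""
    if isinstance(img, GrayImage):
        img = img.crop()
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary spot mask as an 8-bit PNG with 1 -> 255, 0 -> 0."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG written by :func:`save_mask` back to {0,1}."""
    img = load_gray_image(path)
    return (img.pixels > 127).astype(np.uint8)


@dataclass
class RunConfig:
    """Segmentation run parameters.

    clusters
        Number of FCM clusters C.  The relational method needs C >= 3 so
        faint spots are not folded into the background cluster.
    beta
        Central intensity-difference threshold (gray levels) between
        pixels of different clusters; the fuzzy "High" value.
    delta
        Half-width of the trapezoidal transition around beta; 0 gives
        the crisp comparison ``|diff| >= beta``.
    fuzzifier
        FCM weighting exponent m (> 1); m = 2 is the standard choice.
    polarity
        ``spots_dark`` (default) internally inverts intensities so the
        "highest gray value wins" decision rule selects dark gel spots.
    """

    clusters: int = 4
    beta: float = 19.0
    delta: float = 3.0
    fuzzifier: float = 2.0
    tolerance: float = 1e-5
    max_iterations: int = 100
    seed: int = 0
    denoise: bool = False
    polarity: str = "spots_dark"

    def __post_init__(self) -> None:
        if self.clusters < 2:
            raise ValueError("clusters must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0 <= self.beta <= 255:
            raise ValueError("beta must be in [0, 255]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance > 0 and max_iterations >= 1 required")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
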