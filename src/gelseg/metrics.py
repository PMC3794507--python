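"""Segmentation quality metrics.

Implements the Liu–Yang quantitative evaluation function F (region
count, per-region squared color error scaled by region area), MSE/PSNR
between two rasters, the region-mean rendering used to score a
segmentation with PSNR, and pixel/spot-level precision-recall against a
ground-truth mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint cover of the image by connected regions.

    ``labels`` assigns every pixel a region id in 1..n_regions
    (8-connected components of the input label map).
    """

    labels: np.ndarray
    n_regions: int
    areas: np.ndarray

    def __post_init__(self) -> None:
        if self.areas.min(initial=1) < 1 or int(self.areas.sum()) != self.labels.size:
            raise ValueError("regions must be nonempty and cover the image")


def region_partition(label_map: np.ndarray) -> RegionPartition:
    """Split a per-pixel label map into 8-connected regions of equal label."""
    label_map = np.asarray(label_map)
    if label_map.size == 0:
        raise ValueError("empty label map")
    # choose a background value absent from the map so nothing is dropped
    bg = int(label_map.min()) - 1
    regions = measure.label(label_map, connectivity=2, background=bg)
    n = int(regions.max())
    areas = np.bincount(regions.ravel(), minlength=n + 1)[1:]
    return RegionPartition(labels=regions, n_regions=n, areas=areas)


def region_color_errors(img: np.ndarray, part: RegionPartition) -> np.ndarray:
    """Per-region squared color error: sum of squared deviations from
    the region mean intensity."""
    img = np.asarray(img, dtype=np.float64).ravel()
    flat = part.labels.ravel() - 1
    sums = np.bincount(flat, weights=img, minlength=part.n_regions)
    means = sums / part.areas
    return np.bincount(flat, weights=(img - means[flat]) ** 2,
                       minlength=part.n_regions)


def liu_yang_F(img: np.ndarray, part: RegionPartition, sqrt_n: bool = True) -> float:
    """Liu–Yang evaluation function: smaller is better, 0 iff every
    region is internally constant.

    F = sqrt(N) * sum_j e2_j / sqrt(S_j); ``sqrt_n=False`` uses the N
    prefactor instead.
    """
    if part.labels.shape != np.shape(img):
        raise ValueError("partition does not cover the image")
    e2 = region_color_errors(img, part)
    prefactor = math.sqrt(part.n_regions) if sqrt_n else part.n_regions
    return float(prefactor * np.sum(e2 / np.sqrt(part.areas)))


def mse(I: np.ndarray, K: np.ndarray) -> float:
    """Mean squared error between two equally-shaped rasters."""
    I = np.asarray(I, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if I.shape != K.shape:
        raise ValueError(f"shape mismatch: {I.shape} vs {K.shape}")
    return float(np.mean((I - K) ** 2))


def psnr(I: np.ndarray, K: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    err = mse(I, K)
    if err == 0:
        return math.inf
    return 20.0 * math.log10(max_value / math.sqrt(err))


def segmented_render(img: np.ndarray, part: RegionPartition) -> np.ndarray:
    """Replace each pixel by its region's mean intensity (rounded).

    PSNR(img, render) is the reported segmentation PSNR.  Rendering a
    render with the same partition is the identity.
    """
    img_f = np.asarray(img, dtype=np.float64).ravel()
    flat = part.labels.ravel() - 1
    sums = np.bincount(flat, weights=img_f, minlength=part.n_regions)
    means = sums / part.areas
    out = np.clip(np.rint(means[flat]), 0, 255).astype(np.uint8)
    return out.reshape(np.shape(img))


def spot_detection_scores(truth: np.ndarray, pred: np.ndarray) -> dict:
    """Pixel precision/recall plus per-spot recall of a predicted mask.

    A seeded spot (8-connected component of the truth mask) counts as
    recovered when at least half of its pixels are predicted spot.
    Degenerate cases: with no predicted positives precision is 1 if the
    truth is also empty, else 0; with an empty truth recall is 1.
    """
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    tp = int(np.sum(truth & pred))
    n_pred = int(pred.sum())
    n_truth = int(truth.sum())
    precision = (tp / n_pred) if n_pred else (1.0 if n_truth == 0 else 0.0)
    recall = (tp / n_truth) if n_truth else 1.0
    comps = measure.label(truth, connectivity=2)
    n_spots = int(comps.max())
    if n_spots:
        hit = sum(
            1 for s in range(1, n_spots + 1)
            if np.sum(pred[comps == s]) >= 0.5 * np.sum(comps == s)
        )
        per_spot = hit / n_spots
    else:
        per_spot = 1.0
    return {"precision": precision, "recall": recall,
            "per_spot_recall": per_spot, "n_truth_spots": n_spots}
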