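"""End-to-end segmentation of gel images.

Three methods share one estimator:

``fcm``
    Intensity clustering alone; the spot mask is the cluster whose
    center is extreme in the spot direction.
``wfcm``
    Wavelet high-pass sharpening followed by ``fcm``.
``wrfcm``
    Sharpening, clustering with C >= 3, then fuzzy-relational
    refinement of the clusters into the spot mask.

Gel spots are dark on a light background, while the refinement rule
marks the *highest* gray value of a close cross-cluster pair; under the
default ``spots_dark`` polarity intensities are inverted internally so
the rule selects dark spots, and all reported imagery stays in the
original orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .fcm import FcmParams, FcmResult, fcm_fit, hard_labels, init_membership
from .io import GrayImage, RunConfig, ensure_even
from .relational import BetaParams, relational_refine
from .wavelet import DenoiseConfig, highpass_sharpen, wavelet_denoise

logger = logging.getLogger("gelseg")

METHODS = ("fcm", "wfcm", "wrfcm")


@dataclass
class SegmentationResult:
    """Output bundle of one segmentation run."""

    method: str
    label_map: np.ndarray
    spot_mask: np.ndarray
    fcm_result: FcmResult
    region_partition: metrics.RegionPartition
    report: dict


def _as_pixels(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return arr


class GelSpotSegmenter(BaseEstimator):
    """Scikit-learn style segmenter for 2D gel images.

    Parameters
    ----------
    method : {"fcm", "wfcm", "wrfcm"}
    n_clusters : int or None
        FCM cluster count C; defaults to 2 for fcm/wfcm and 4 for wrfcm.
    beta, delta : float
        Central threshold and fuzzy half-width of the relational
        closeness comparison (gray levels); wrfcm only.
    m, tol, max_iter : FCM hyperparameters.
    denoise : bool
        Apply wavelet shrinkage before everything else.
    denoise_config : DenoiseConfig or None
        Defaults to (heursure, hard, mln, level 2).
    polarity : {"spots_dark", "spots_bright"}
    refine : bool
        Disable to stop wrfcm after clustering (then its labeling equals
        wfcm's under the same seed).
    random_state : int

    Attributes
    ----------
    labels_ : per-pixel cluster labels in [0, C), clusters ordered by
        ascending center on the working (polarity-adjusted) scale
    spot_mask_ : binary spot mask, original orientation
    cluster_centers_ : centers on the working scale
    fcm_result_ : FcmResult over the gray-level histogram
    n_clusters_ : effective cluster count used
    """

    def __init__(self, method: str = "wrfcm", n_clusters: int | None = None,
                 beta: float = 19.0, delta: float = 3.0, m: float = 2.0,
                 tol: float = 1e-5, max_iter: int = 100, denoise: bool = False,
                 denoise_config: DenoiseConfig | None = None,
                 polarity: str = "spots_dark", refine: bool = True,
                 random_state: int = 0):
        self.method = method
        self.n_clusters = n_clusters
        self.beta = beta
        self.delta = delta
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.denoise = denoise
        self.denoise_config = denoise_config
        self.polarity = polarity
        self.refine = refine
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _resolved_clusters(self) -> int:
        if self.n_clusters is not None:
            c = int(self.n_clusters)
        else:
            c = 4 if self.method == "wrfcm" else 2
        if c < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.method == "wrfcm" and self.refine and c < 3:
            raise ValueError("wrfcm requires n_clusters >= 3")
        return c

    def fit(self, X, y=None) -> "GelSpotSegmenter":
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        C = self._resolved_clusters()
        img = _as_pixels(X)
        if img.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        img, pad_b, pad_r = ensure_even(img)

        work = (255 - img) if self.polarity == "spots_dark" else img
        if self.denoise:
            work = wavelet_denoise(work, self.denoise_config or DenoiseConfig())
        if self.method in ("wfcm", "wrfcm"):
            work = highpass_sharpen(work)

        levels, counts = np.unique(work.ravel(), return_counts=True)
        c_eff = min(C, len(levels))
        if c_eff < C:
            logger.warning("only %d distinct gray levels; clamping C from %d",
                           len(levels), C)
        degenerate = c_eff < 2
        if degenerate:
            logger.warning("constant image: single effective cluster, empty mask")
            res = FcmResult(U=np.ones((len(levels), 1)),
                            centers=np.array([float(levels[0])]),
                            objective_trace=[0.0], iterations=0, converged=True)
        else:
            # exact histogram form of per-pixel FCM: weight each gray
            # level by its count
            params = FcmParams(C=c_eff, m=self.m, tol=self.tol,
                               max_iter=self.max_iter, seed=self.random_state)
            res = fcm_fit(levels.astype(np.float64), params,
                          weights=counts.astype(np.float64))
            order = np.argsort(res.centers)
            res = FcmResult(U=res.U[:, order], centers=res.centers[order],
                            objective_trace=res.objective_trace,
                            iterations=res.iterations, converged=res.converged)

        level_labels = hard_labels(levels.astype(np.float64), res.centers)
        lut = np.zeros(256, dtype=np.int64)
        lut[levels] = level_labels
        label_map = lut[work]

        if degenerate:
            mask = np.zeros(img.shape, dtype=np.uint8)
        elif self.method == "wrfcm" and self.refine:
            mask = relational_refine(work, res, BetaParams(self.beta, self.delta))
        else:
            # spot side = brightest cluster on the working scale
            mask = (label_map == int(np.argmax(res.centers))).astype(np.uint8)

        crop = lambda a: a[:a.shape[0] - pad_b or None, :a.shape[1] - pad_r or None]
        self.labels_ = crop(label_map)
        self.spot_mask_ = crop(mask)
        self.cluster_centers_ = res.centers
        self.fcm_result_ = res
        self.n_clusters_ = c_eff
        self._work_image_ = crop(work)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).spot_mask_


def _final_label_map(result_labels: np.ndarray, mask: np.ndarray,
                     n_clusters: int) -> np.ndarray:
    """Cluster labels with spot pixels overridden to a dedicated label."""
    out = result_labels.copy()
    out[mask.astype(bool)] = n_clusters
    return out


def evaluate(img, labels: np.ndarray, mask: np.ndarray, n_clusters: int,
             truth: np.ndarray | None = None) -> tuple[dict, metrics.RegionPartition]:
    """Score a segmentation: Liu-Yang F over the 8-connected regions of
    the spot-over-clusters label map, PSNR of the region-mean render
    against the original, and mask precision/recall when truth given."""
    img = _as_pixels(img)
    if labels.shape != img.shape or mask.shape != img.shape:
        raise ValueError("labels/mask shape must match the image")
    part = metrics.region_partition(_final_label_map(labels, mask, n_clusters))
    render = metrics.segmented_render(img, part)
    report = {
        "F": metrics.liu_yang_F(img, part),
        "PSNR_dB": metrics.psnr(img, render),
        "n_regions": part.n_regions,
        "n_spot_pixels": int(mask.sum()),
    }
    if truth is not None:
        report.update(metrics.spot_detection_scores(truth, mask))
    return report, part


def _segment(method: str, img, cfg: RunConfig,
             truth: np.ndarray | None = None) -> SegmentationResult:
    seg = GelSpotSegmenter(
        method=method, n_clusters=cfg.clusters, beta=cfg.beta, delta=cfg.delta,
        m=cfg.fuzzifier, tol=cfg.tolerance, max_iter=cfg.max_iterations,
        denoise=cfg.denoise, polarity=cfg.polarity, random_state=cfg.seed,
    ).fit(img)
    report, part = evaluate(img if not isinstance(img, GrayImage) else img.crop(),
                            seg.labels_, seg.spot_mask_, seg.n_clusters_,
                            truth=truth)
    report["method"] = method
    return SegmentationResult(method=method, label_map=seg.labels_,
                              spot_mask=seg.spot_mask_, fcm_result=seg.fcm_result_,
                              region_partition=part, report=report)


def segment_fcm(img, cfg: RunConfig, truth=None) -> SegmentationResult:
    """Plain FCM baseline (conventionally C = 2)."""
    return _segment("fcm", img, cfg, truth)


def segment_wfcm(img, cfg: RunConfig, truth=None) -> SegmentationResult:
    """Wavelet FCM baseline: highpass-sharpen, then FCM."""
    return _segment("wfcm", img, cfg, truth)


def segment_wrfcm(img, cfg: RunConfig, truth=None) -> SegmentationResult:
    """Wavelet relational FCM: sharpen, cluster with C >= 3, refine."""
    if cfg.clusters < 3:
        raise ValueError("wrfcm requires clusters >= 3")
    return _segment("wrfcm", img, cfg, truth)


def sobel_gradient(img) -> np.ndarray:
    """Sobel gradient-magnitude rendering (display only; the
    segmentation itself always runs on intensity images)."""
    from scipy import ndimage
    img = _as_pixels(img).astype(np.float64)
    g = np.hypot(ndimage.sobel(img, axis=0), ndimage.sobel(img, axis=1))
    if g.max() > 0:
        g = g / g.max() * 255.0
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)
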