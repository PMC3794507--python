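"""Haar wavelet analysis, high-pass sharpening, shrinkage denoising and
the genetic search over denoising parameters.

The sharpening step decomposes the image into one level of LL/LH/HL/HH
subbands, zeroes the approximation (LL) band, inverts the transform to
obtain a zero-mean high-pass image L1, and adds L1 back to the original.
Denoising is orthogonal wavelet shrinkage with the Donoho–Johnstone
``heursure``/``minimax`` threshold rules, soft or hard thresholding and
three noise-rescaling modes, optionally tuned by a small genetic
algorithm with PSNR as fitness.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import psnr

logger = logging.getLogger("gelseg")

WAVELET = "haar"
# Length-2 Haar filters never straddle the boundary of an even-sized
# signal, so periodization gives exact orthonormality at every level.
_MODE = "periodization"

THRESHOLD_RULES = ("heursure", "minimax")
THRESHOLD_MODES = ("soft", "hard")
RESCALE_MODES = ("one", "sln", "mln")


@dataclass(frozen=True)
class SubbandSet:
    """One level of 2-D wavelet coefficients."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    wavelet_name: str = WAVELET
    level: int = 1

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.LL, self.LH, self.HL, self.HH)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")
        if self.level < 1:
            raise ValueError("level must be >= 1")


def _check_even(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D array, got shape {img.shape}")
    if img.shape[0] % 2 or img.shape[1] % 2:
        raise ValueError(f"dimensions must be even, got {img.shape}")
    return img


def haar_dwt2(img: np.ndarray) -> SubbandSet:
    """Single-level orthonormal 2-D Haar decomposition.

    Energy is conserved: the sum of squares over all four subbands
    equals the sum of squares of the input.
    """
    img = _check_even(img)
    LL, (LH, HL, HH) = pywt.dwt2(img, WAVELET, mode=_MODE)
    return SubbandSet(LL=LL, LH=LH, HL=HL, HH=HH)


def haar_idwt2(bands: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`haar_dwt2`."""
    return pywt.idwt2((bands.LL, (bands.LH, bands.HL, bands.HH)), WAVELET, mode=_MODE)


def highpass_sharpen(img: np.ndarray) -> np.ndarray:
    """Sharpen by adding the LL-suppressed reconstruction to the image.

    The high-pass image L1 (inverse transform with LL := 0) has zero
    mean, so a constant image is returned unchanged.  Output is rounded
    and clipped to [0, 255].
    """
    img = _check_even(img)
    bands = haar_dwt2(img)
    l1 = haar_idwt2(SubbandSet(LL=np.zeros_like(bands.LL), LH=bands.LH,
                               HL=bands.HL, HH=bands.HH))
    return np.clip(np.rint(img + l1), 0, 255).astype(np.uint8)


class HighpassSharpener(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapper around :func:`highpass_sharpen`."""

    def fit(self, X: np.ndarray, y=None) -> "HighpassSharpener":
        _check_even(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return highpass_sharpen(X)


# ---------------------------------------------------------------------------
# threshold selection (Donoho–Johnstone rules)
# ---------------------------------------------------------------------------

def _sure_threshold(x: np.ndarray) -> float:
    """Threshold minimizing Stein's unbiased risk estimate, for unit
    noise scale."""
    n = x.size
    sx2 = np.sort(np.abs(x)) ** 2
    cum = np.cumsum(sx2)
    k = np.arange(1, n + 1)
    risks = (n - 2.0 * k + cum + (n - k) * sx2) / n
    return float(np.sqrt(sx2[int(np.argmin(risks))]))


def select_threshold(coeffs: np.ndarray, rule: str, sigma: float) -> float:
    """Pick a shrinkage threshold for a vector of detail coefficients.

    ``minimax``: sigma * (0.3936 + 0.1829 * log2(n)) for n > 32, else 0.
    ``heursure``: if the coefficients are sparse by the usual energy
    criterion, the universal threshold sigma*sqrt(2 ln n); otherwise the
    smaller of the SURE-minimizing and universal thresholds.
    """
    x = np.asarray(coeffs, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty coefficient list")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"rule must be one of {THRESHOLD_RULES}")
    n = x.size
    if rule == "minimax":
        return sigma * (0.3936 + 0.1829 * math.log2(n)) if n > 32 else 0.0
    xn = x / sigma
    universal = math.sqrt(2.0 * math.log(n))
    eta = (np.sum(xn**2) - n) / n
    crit = math.log2(n) ** 1.5 / math.sqrt(n)
    if eta < crit:  # sparse signal: SURE unreliable, use universal
        lam = universal
    else:
        lam = min(_sure_threshold(xn), universal)
    return sigma * lam


def apply_threshold(coeffs: np.ndarray, lam: float, mode: str) -> np.ndarray:
    """Hard (keep-or-kill) or soft (shrink-by-lambda) thresholding."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"mode must be one of {THRESHOLD_MODES}")
    w = np.asarray(coeffs, dtype=np.float64)
    if mode == "hard":
        return np.where(np.abs(w) <= lam, 0.0, w)
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiseConfig:
    """Orthogonal wavelet shrinkage parameters.

    rule
        Threshold selection: ``heursure`` or ``minimax``.
    thresholding
        ``soft`` or ``hard``.
    rescaling
        Noise-scale estimation: ``one`` (fixed at 1), ``sln`` (single
        estimate from the finest diagonal details) or ``mln``
        (level-dependent estimates).
    level
        Decomposition depth (>= 1).
    """

    rule: str = "heursure"
    thresholding: str = "hard"
    rescaling: str = "mln"
    level: int = 2

    def __post_init__(self) -> None:
        if self.rule not in THRESHOLD_RULES:
            raise ValueError(f"rule must be one of {THRESHOLD_RULES}")
        if self.thresholding not in THRESHOLD_MODES:
            raise ValueError(f"thresholding must be one of {THRESHOLD_MODES}")
        if self.rescaling not in RESCALE_MODES:
            raise ValueError(f"rescaling must be one of {RESCALE_MODES}")
        if self.level < 1:
            raise ValueError("level must be >= 1")

    def to_json(self) -> str:
        return json.dumps({"rule": self.rule, "thresholding": self.thresholding,
                           "rescaling": self.rescaling, "level": self.level})

    @classmethod
    def from_json(cls, s: str) -> "DenoiseConfig":
        return cls(**json.loads(s))


def _mad_sigma(d: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of detail
    coefficients (Gaussian calibration 0.6745)."""
    return float(np.median(np.abs(d)) / 0.6745)


def max_decomposition_level(shape: tuple[int, int]) -> int:
    return int(math.floor(math.log2(min(shape))))


def wavelet_denoise(img: np.ndarray, cfg: DenoiseConfig,
                    threshold_override: float | None = None) -> np.ndarray:
    """Multi-level Haar shrinkage denoising of an 8-bit image.

    Detail subbands are thresholded per level and orientation with
    ``select_threshold`` / ``apply_threshold``; the approximation band
    is untouched.  ``threshold_override`` forces a fixed lambda for all
    subbands (diagnostic use; 0 reproduces the input exactly).
    """
    img = _check_even(img)
    if cfg.level > max_decomposition_level(img.shape):
        raise ValueError(
            f"level {cfg.level} too deep for image of shape {img.shape}")
    coeffs = pywt.wavedec2(img, WAVELET, mode=_MODE, level=cfg.level)
    # coeffs = [LL_n, (LH_n, HL_n, HH_n), ..., (LH_1, HL_1, HH_1)]
    finest_hh = coeffs[-1][2]
    sigma_sln = _mad_sigma(finest_hh)
    new = [coeffs[0]]
    for bands in coeffs[1:]:
        if cfg.rescaling == "one":
            sigma = 1.0
        elif cfg.rescaling == "sln":
            sigma = sigma_sln
        else:  # mln: per-level estimate from this level's diagonal band
            sigma = _mad_sigma(bands[2])
        out = []
        for band in bands:
            if threshold_override is not None:
                lam = threshold_override
            elif sigma <= 0:
                lam = 0.0  # no noise evidence at this level
            else:
                lam = select_threshold(band.ravel(), cfg.rule, sigma)
            out.append(apply_threshold(band, lam, cfg.thresholding))
        new.append(tuple(out))
    rec = pywt.waverec2(new, WAVELET, mode=_MODE)
    return np.clip(np.rint(rec), 0, 255).astype(np.uint8)


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`wavelet_denoise`."""

    def __init__(self, rule: str = "heursure", thresholding: str = "hard",
                 rescaling: str = "mln", level: int = 2):
        self.rule = rule
        self.thresholding = thresholding
        self.rescaling = rescaling
        self.level = level

    def _config(self) -> DenoiseConfig:
        return DenoiseConfig(self.rule, self.thresholding, self.rescaling, self.level)

    def fit(self, X: np.ndarray, y=None) -> "WaveletDenoiser":
        img = _check_even(X)
        if self._config().level > max_decomposition_level(img.shape):
            raise ValueError("decomposition level too deep for image")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return wavelet_denoise(X, self._config())


# ---------------------------------------------------------------------------
# genetic search over the 48-point denoising configuration space
# ---------------------------------------------------------------------------

@dataclass
class GaConfig:
    """Hyperparameters of the genetic search.

    The space is tiny (2 rules x 2 threshold types x 3 rescalings x <= 4
    levels = 48 chromosomes), so modest defaults explore it fully.
    """

    population_size: int = 20
    generations: int = 30
    mutation_rate: float = 0.1
    seed: int = 0
    elitism: int = 1
    tournament_size: int = 3

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


_GENE_CHOICES = (THRESHOLD_RULES, THRESHOLD_MODES, RESCALE_MODES)


def _chromosome_to_config(chrom: tuple) -> DenoiseConfig:
    return DenoiseConfig(rule=chrom[0], thresholding=chrom[1],
                         rescaling=chrom[2], level=chrom[3])


def denoise_config_space(max_level: int = 4):
    """All admissible denoising configurations up to ``max_level``."""
    for rule, thr, res, lev in itertools.product(
            THRESHOLD_RULES, THRESHOLD_MODES, RESCALE_MODES,
            range(1, max_level + 1)):
        yield DenoiseConfig(rule, thr, res, lev)


class GaDenoiseTuner(BaseEstimator):
    """Genetic search for the denoising configuration maximizing PSNR.

    fit(X, y) evaluates PSNR(denoise(X, config), y) as fitness, where
    ``y`` is the reference image (clean ground truth when available,
    otherwise the input itself).  With elitism the best fitness per
    generation is non-decreasing.

    Attributes
    ----------
    best_config_ : DenoiseConfig
    best_fitness_ : float
    fitness_trace_ : list of per-generation best fitness
    """

    def __init__(self, population_size: int = 20, generations: int = 30,
                 mutation_rate: float = 0.1, elitism: int = 1,
                 tournament_size: int = 3, random_state: int = 0):
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.tournament_size = tournament_size
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "GaDenoiseTuner":
        img = _check_even(X)
        ref = img if y is None else np.asarray(y, dtype=np.float64)
        if ref.shape != img.shape:
            raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
        rng = np.random.default_rng(self.random_state)
        max_level = min(4, max_decomposition_level(img.shape))
        levels = tuple(range(1, max_level + 1))
        cache: dict[tuple, float] = {}

        def fitness(chrom: tuple) -> float:
            if chrom not in cache:
                den = wavelet_denoise(img, _chromosome_to_config(chrom))
                cache[chrom] = psnr(ref, den)
            return cache[chrom]

        def random_chrom() -> tuple:
            return (THRESHOLD_RULES[rng.integers(2)],
                    THRESHOLD_MODES[rng.integers(2)],
                    RESCALE_MODES[rng.integers(3)],
                    int(rng.choice(levels)))

        pop = [random_chrom() for _ in range(self.population_size)]
        trace: list[float] = []
        for _ in range(self.generations):
            fits = np.array([fitness(c) for c in pop])
            order = np.argsort(-fits)
            trace.append(float(fits[order[0]]))
            elite = [pop[i] for i in order[: self.elitism]]
            children = list(elite)
            while len(children) < self.population_size:
                parents = []
                for _ in range(2):
                    idx = rng.integers(len(pop), size=self.tournament_size)
                    parents.append(pop[int(idx[np.argmax(fits[idx])])])
                child = tuple(parents[int(rng.integers(2))][g] for g in range(4))
                genes = list(child)
                for g in range(4):
                    if rng.random() < self.mutation_rate:
                        if g < 3:
                            genes[g] = _GENE_CHOICES[g][rng.integers(len(_GENE_CHOICES[g]))]
                        else:
                            genes[g] = int(rng.choice(levels))
                children.append(tuple(genes))
            pop = children
        fits = np.array([fitness(c) for c in pop])
        best = pop[int(np.argmax(fits))]
        # elitism guarantees the final population holds the best-ever chromosome
        self.best_config_ = _chromosome_to_config(best)
        self.best_fitness_ = float(np.max(fits))
        self.fitness_trace_ = trace + [self.best_fitness_]
        return self


def ga_optimize_denoise(img: np.ndarray, reference: np.ndarray,
                        cfg: GaConfig | None = None) -> DenoiseConfig:
    """Return the denoising configuration found by the genetic search."""
    cfg = cfg or GaConfig()
    tuner = GaDenoiseTuner(
        population_size=cfg.population_size, generations=cfg.generations,
        mutation_rate=cfg.mutation_rate, elitism=cfg.elitism,
        tournament_size=cfg.tournament_size, random_state=cfg.seed,
    ).fit(img, reference)
    return tuner.best_config_
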