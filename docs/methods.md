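# Methods

## Model and assumptions

The segmenter treats a gel scan as a 1-D mixture problem on pixel
intensity: protein spots are dark local dips on a smooth, lighter
background, and cluster structure in the gray-level histogram separates
spot-ish from background-ish intensities.  Spatial context is used only
twice — in the wavelet sharpening front end and in the connected-region
extraction for the quality metrics — never in the clustering or the
relational decision itself.  This is a deliberate property: a spot
survives segmentation no matter how small it is, as long as its gray
levels separate from the background, which is what rescues faint ghost
spots.

### Phase 1: wavelet high-pass sharpening

One level of an orthonormal 2-D Haar transform yields subbands
LL/LH/HL/HH.  Zeroing LL and inverting gives the zero-mean high-pass
image L1; the working image becomes `clip(round(I + L1), 0, 255)`.  The
transform uses periodized boundary handling: for the length-2 Haar
filter on even-sized images this is identical to symmetric extension
(no 2x2 analysis block straddles a boundary) and it keeps perfect
reconstruction and energy conservation exact at every level of the
multilevel denoiser.  Decomposition depth for sharpening is 1 — the
minimal depth that produces the subband quartet; deeper sharpening
would progressively turn the image into pure texture.

### Phase 2: fuzzy c-means (FCM)

Standard FCM on scalar intensities with fuzzifier `m = 2`, C clusters
(default 4 for the relational method, 2 for the baselines), convergence
when the max-abs membership change drops below `tol = 1e-5` (entrywise
max norm; cap 100 iterations).  A point coinciding with one or more
centers splits its membership equally among the coincident centers; a
cluster column losing all mass is reinitialized at random and logged.
Constant images converge immediately to equal centers and uniform
memberships and yield an empty spot mask.

Fitting runs on the gray-level histogram: each of the ≤ 256 present
levels is one weighted point.  Because the objective and both updates
depend on data only through value and multiplicity, this is *exactly*
per-pixel FCM (verified against the per-pixel computation in the test
suite), and it makes 512x512 images cheap.

Hard labels are argmax membership with ties broken toward the larger
center (the spot side after inversion).  For scalar data argmax
membership equals nearest center, so labels are computed directly from
the centers.

### Phase 3: fuzzy-relational refinement

For gray levels g1, g2 carried by pixels in different clusters, the
relation value is `|g1 − g2|`, fuzzified by trapezoidal High/Low
membership functions centred on β: High ramps 0→1 over
`[β−δ, β+δ]` (right shoulder above 255 so every larger difference is
fully High), Low is the mirror image.  Defaults β = 19, δ = 3; the
0.5-cut makes the crisp decision exactly `diff ≥ β`, and δ = 0
reproduces the fully crisp sweep.

Stage 1 marks, for every cross-cluster pair whose difference is High,
the larger gray level as spot.  Stage 2 iterates the propagation rule —
a Low cross-cluster pair with exactly one marked level marks the other
— to a fixed point; the marked set grows monotonically and is bounded
by 256 levels, so termination is immediate.  Pixel pairs collapse
exactly onto gray-level pairs (the relation depends only on gray value
and cluster), reducing ~10^10 pixel comparisons at 512² to ≤ 256² with
provably identical output; the equivalence is oracle-tested against the
brute-force all-pairs classifier.

Gel spots are dark but the decision rule marks the *higher* gray value,
so under the default `spots_dark` polarity the image is inverted
(v → 255−v) before phases 1–3 and all reported imagery is un-inverted.
Within-cluster pairs are never compared; the relation is defined across
clusters only.

## Denoising and its tuning

Optional preprocessing is orthogonal Haar shrinkage: per level and
orientation, detail coefficients are thresholded with the
Donoho–Johnstone rules — `minimax` (λ = σ(0.3936 + 0.1829·log2 n) for
n > 32, else 0) or `heursure` (universal threshold σ√(2 ln n) when the
energy criterion flags sparsity, else min(SURE, universal)) — under
soft or hard thresholding.  The noise scale σ is the median absolute
detail coefficient / 0.6745, taken from the finest diagonal band
(`sln`), per level (`mln`), or fixed at 1 (`one`).  The approximation
band is untouched.  Default configuration: heursure, hard, mln,
level 2.

The four-parameter space (2 rules × 2 threshold types × 3 rescalings ×
levels 1–4 = 48 points) is searched by a small genetic algorithm with
PSNR as fitness: population 20, 30 generations, tournament size 3,
uniform crossover, mutation rate 0.1, elitism 1.  Elitism makes the
per-generation best non-decreasing, and on this tiny space the search
provably-in-practice attains the exhaustive optimum (asserted against
full enumeration in the tests).  The PSNR reference is the clean ground
truth when one exists (synthetic data); otherwise the noisy input
itself is used, which still yields a reproducible, if conservative,
ranking.

## Quality metrics

Liu–Yang `F = √N · Σ_j e_j²/√S_j` over the 8-connected components of
the final label map (cluster labels with spot pixels overridden by a
dedicated spot label); `e_j²` is the summed squared deviation from the
region's mean intensity.  F = 0 iff every region is internally
constant.  The √N prefactor follows the "divided by the square root of
the area" reading; a switch (`sqrt_n=False`) gives the N-prefactor
variant.  Segmentation PSNR compares the original image with its
region-mean rendering; identical images return an explicit +inf
sentinel.  Against synthetic ground truth the package also reports
pixel precision/recall and per-spot recall (a seeded spot counts as
recovered when ≥ 50% of its half-maximum disk is predicted spot).

## Synthetic gels

The generator emulates 8-bit gel scans: a smooth quadratic background
surface around gray level 200 with ±20 tilt, isotropic Gaussian dips of
80–150 gray levels (strong spots) and 10–30 (ghost spots) with radii
σ ∈ [2.5, 5] px at integer centers spaced ≥ 2(σ_i + σ_j) apart
(rejection-sampled; σ is redrawn per attempt so crowded layouts fall
back to smaller spots), plus additive Gaussian noise drawn last so the
clean counterpart of a gel is reproducible from the same seed.  The
truth mask is the analytic half-maximum disk (radius σ√(2 ln 2)) of
each spot.  The default benchmark is seven 256×256 gels of 40 spots
spanning noise sd {2, 5, 10} × ghost fraction {0.2, 0.5} plus a
30-strong/10-ghost middle condition.

What the generator does **not** emulate: gel warping, streaks,
anisotropic or overlapping spots, saturation, and spatially correlated
noise.  Passing the benchmark therefore demonstrates correct behaviour
of the algorithmic chain under the stated conditions, not performance
on real scanner artefacts.

## Numerical choices and degenerate inputs

- Odd image dimensions are symmetrically padded to even and cropped
  back on output; padding-then-cropping is the identity.
- 16-bit inputs are linearly rescaled to 8 bits with a warning;
  multi-channel inputs are averaged to luminance.
- Requested C larger than the number of distinct gray levels is clamped
  (with a warning); fewer than 2 effective levels yields an empty mask.
- Hard thresholding kills coefficients with |w| ≤ λ (boundary
  inclusive); soft thresholding shrinks by λ.
- Degenerate trapezoid edges (coincident breakpoints) act as steps,
  giving the crisp comparison in the δ → 0 limit.
- Benchmark problem sizes (256×256, 7 gels; 64×64 for the denoise
  tuning check; 16×16 for the brute-force equivalence oracle) were
  chosen so the whole suite runs comfortably on a single CPU while
  still exercising every phase at realistic scale.

## Known limitations

- The relational stage optimizes recall of faint spots at the cost of
  pixel precision: any gray level β above a cross-cluster partner is
  marked.  Downstream quantification should treat the mask as a spot
  *detector*, not an area estimator.
- Clustering ignores spatial smoothness entirely; heavy-tailed or
  correlated noise can seed spurious marked levels (mitigated by the
  denoising front end).
- The GA tuner's guarantee of matching the exhaustive optimum is only
  meaningful on the small discrete space it searches; it is not a
  general-purpose optimizer.
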