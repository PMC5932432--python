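# Methods

## Matched-filter detection

The detector assumes a vessel is locally a straight, dark valley with a
Gaussian cross-section of spread σ (pixels) on a locally flat background.
The template evaluates `-exp(-x²/2σ²)` across the vessel and is constant
along it over a segment of length L; the trails are cut at width T. T and L
are full widths in pixels; even values are rounded up to the next odd
integer so the template is centered on a pixel. All κ orientations share
one square grid whose side is the smallest odd integer ≥ max(L, T); a
rotated kernel is produced by evaluating the continuous template at
back-rotated grid coordinates (analytic resampling — no image-space
interpolation), with support the back-rotated L×T rectangle intersected
with the grid. Corners of the rotated rectangle that fall outside the grid
are clipped; the mass lost is in the Gaussian trails and is negligible for
the shipped parameterizations.

The mean over the support is subtracted, making every kernel zero-sum:
the response to a constant image is numerically zero, and smooth
illumination gradients are strongly suppressed. Filtering is correlation
(no kernel flip — immaterial here because the template has 180° point
symmetry, but fixed for reproducibility) under symmetric-reflect border
padding, computed by FFT convolution; a brute-force spatial correlation
serves as the oracle in the tests. Vessels are dark and the template is
negative, so the response is positive on vessels with the image in its
native polarity.

**A property worth knowing:** the matched response of a σ-2 valley crosses
zero at ≈1.6σ from the centerline and is negative beyond, while a perfectly
flat background responds exactly 0. On noiseless synthetic images the outer
ring of the 2σ ground-truth band therefore ranks *below* the background and
single-scale ROC areas saturate around 0.94–0.95; any amount of background
texture (noise, neighboring structures) lifts this, and the fusion network
learns the ring's signature across scales and resolves it entirely. This is
the cleanest illustration of why fusing multiscale responses outperforms
thresholding any single response.

Scale selectivity is relative, not absolute: because kernels are zero-sum
but not energy-normalized, the raw response grows with kernel support, so a
thin vessel's strongest layer may sit slightly above its true σ. The stack
still orders calibers correctly (a thin vessel's best layer is strictly
below a thick vessel's), which is all the fusion stage needs.

## Fusion network

A pixel's feature vector is its n-scale response vector (default n = 11,
σ from 1.5 to 2.5 in steps of 0.1 — the explicit scale list is used even
though such ranges are sometimes counted as ten). Features are z-scored per
scale with constants estimated on the training sample and frozen into the
model; raw magnitudes vary across scales by construction, and normalization
can be disabled (`normalize_inputs=False`) to study the difference.

The network is a fixed four-layer perceptron (inputs, two hidden layers,
one output neuron) with logistic activations throughout — the natural
choice for a thresholdable score in (0, 1). Training minimizes mean squared
error against {0, 1} labels with mini-batch gradient descent plus momentum
(default: learning rate 0.5, momentum 0.9, batch 256, 200 epochs), Glorot
uniform initialization, and every random draw (initialization, pixel
sampling, shuffling) derived from one recorded seed, so retraining is
bitwise reproducible. A full-batch Levenberg–Marquardt optimizer is
available (`optimizer="lm"`) for small sample sets; its memory grows as
n_samples × n_parameters, so gradient descent remains the default. Optional
early stopping monitors validation A_z with patience 20 when a validation
fraction is configured; by default all sampled pixels train for the fixed
epoch budget.

Pixel sampling takes every vessel pixel of every training image plus
`class_balance` (default 1.0) times as many uniformly drawn background
pixels — vessel pixels are the minority class and would otherwise be
swamped. The two hidden-layer widths are chosen by exhaustive search over
[1, 10]² scored by pooled training-set A_z, each cell trained once;
exact ties break toward fewer total neurons, then a smaller first layer.
Scoring on the training set is faithful to the original protocol but
overfit-prone; the generalization test (train/test A_z gap ≤ 0.02 on a
20/20 phantom split) guards the default architecture. The shipped default
(3, 8) is the optimum reported for 11-scale angiogram features.

## Thresholding

Global methods operate on a 256-bin histogram built by min–max rescaling
the response to [0, 255] with round-half-up binning; the binning map is
recorded so a bin threshold t converts back to a response cutoff, and the
mask is `bin(response) > t` (vessels are HIGH in the response). Ties among
equally optimal t always break toward the smallest t, making every global
method a pure function of the histogram; inside the optimizing methods the
class weights are computed with direct slice sums so that thresholds
separated only by empty bins produce bit-identical objectives and the tie
rule is exact. Bin-index thresholds are invariant to affine rescaling of
the response because the histogram map absorbs it.

Method-specific notes:

- **Pal & Pal** is implemented as the exponential-entropy variant
  (maximize Σ p·e^(1-p) within each class) to keep it distinct from
  Kapur's Shannon form; the original citation admits several readings and
  this interpretation is deliberate.
- **Tsai moments** uses the closed form; a numerically negative
  discriminant is clamped to zero with a warning.
- **Concavity** takes the deepest local maximum of (upper convex hull −
  histogram). A histogram that is concave as a function coincides with its
  hull; that degenerate case raises an error and `segment` falls back to
  Otsu.
- **Sauvola** keeps the standard formula m·(1 + k·(s/R − 1)), which
  *lowers* the threshold where the local spread is small — verbal
  descriptions sometimes state the opposite sense; the formula wins.
- Local methods (window 15; Niblack k = −0.2, Sauvola k = 0.5 and R = 0.5
  for unit-range responses, White–Rohrer bias 1.0 — standard literature
  defaults, exposed in config) compute windowed means via integral images
  anchored at the image minimum, so windows that are flat at the anchor
  give exactly zero sums and the strict `>` decisions are deterministic.
- Constant responses yield an all-background mask with a logged warning
  rather than an error at the pipeline level.

## Evaluation

The ROC curve sweeps n + 1 evenly spaced cutoffs (default 256, matching
8-bit convention) over the response range from high to low, with predicted
positive = response ≥ cutoff, and appends the (0,0)/(1,1) endpoints. A_z is
the trapezoidal sum over FPF-sorted points; a left-endpoint rule is
available and biases A_z low. The trapezoid gives tied blocks (e.g. a flat
background) the proper half credit and agrees with the Mann–Whitney
U/(n₀n₁) statistic to < 0.005 in simulation. Because cutoffs are evenly
spaced in *value*, A_z is invariant under monotone transforms of the
response only up to re-binning — about 3·10⁻⁵ under a severe warp (exp)
at 4096 cutoffs, and smaller for mild ones; rank-exact invariance would
require quantile cutoffs, which the sweep deliberately does not use.
Dataset-level A_z pools all pixels of all images by default (per-image
averaging is available) — with one pooled figure per set being the
convention the reported numbers follow.

## Phantom generator

Each phantom emulates the salient difficulties of an X-ray angiogram on a
300×300 frame: 5 vessel branches as smooth random spline paths crossing the
frame, per-vessel Gaussian half-width σ_v drawn from 1.5–2.5 px (the range
the default scale stack targets), profile depth 0.4 (contrast) subtracted
from a 0.75 background, an illumination field of two random low-frequency
sinusoids (amplitude 0.1), and i.i.d. Gaussian noise (σ = 0.03). Distances
to centerlines are exact point-to-segment distances (KD-tree prefiltered),
so a noiseless straight vessel's cross-section matches the analytic profile
to raster tolerance; profile contributions beyond 6σ_v (< 2·10⁻⁸) are
skipped. Ground truth is the set of pixels within 2σ_v of a centerline
(≈95% of profile mass) and a per-pixel map records the true σ_v — an
explicit, fixed stand-in for expert outlining. Everything derives from one
seed; datasets derive per-image child seeds from a master seed and rerun
byte-identically.

What the phantoms do *not* model: X-ray projection physics, Poisson photon
statistics, stenoses and aneurysms, catheter and rib shadows, and the
texture of real myocardial background. Passing on phantoms therefore shows
the pipeline's internal consistency and the qualitative multiscale-fusion
benefit, not clinical-grade performance.

## Problem sizes and numerical choices

The shipped studies use 20 training + 20 test phantoms at 300×300 with the
11-scale default bank, 100-epoch training at batch 1024, and 10 seeded
retrainings for the stability table — sizes chosen so a full study runs in
minutes on one core while keeping ~1.8 million pooled test pixels per A_z
estimate. Kernel zero-sum holds to 10⁻¹⁰; FFT correlation matches spatial
correlation to 10⁻¹⁰ on unit-range images; ROC estimates use 256 cutoffs
(512–4096 where an oracle comparison demands finer resolution). Degenerate
inputs (constant images, single-class ground truth, single-occupied-bin
histograms) raise typed errors at the library level and are absorbed into
warnings + all-background masks at the pipeline level.

## Known limitations

- Single-scale A_z on perfectly noiseless phantoms saturates near 0.94–0.95
  (negative-ring effect above); this is inherent to zero-sum matched
  filtering against a 2σ ground-truth band, not an implementation artifact.
- The architecture search trains each grid cell once; a noisy cell A_z can
  in principle displace the true optimum.
- Levenberg–Marquardt is practical only for small pixel samples.
- Approximate presets (`al_rawi`, `gmf_evol`, `gmf_entropy`) stand in for
  published methods whose final optimized parameters were never printed;
  they use search-space midpoints and are flagged `approximate` in code.
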