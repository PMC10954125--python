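# Methods

This note documents the models and procedures implemented in `dermpipe`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, the numerical choices, and the known limitations.

## Speckle model and denoising

Dermoscopy-style speckle is modeled multiplicatively: the observed image
is `A0 = A · n` with a unit-mean noise factor `n` drawn i.i.d. per pixel.
The generator draws `n` from a Gamma distribution with mean 1 and
variance `speckle_var` (shape `1/var`), which keeps the factor positive;
the distribution family is a modeling choice — only the first two
moments are relied on anywhere.

Denoising iterates the explicit Perona–Malik scheme on a 4-neighborhood
with exponential conduction `g(d) = exp(−(d/κ)²)` and reflecting
(edge-clamped) borders, written in flux form so total intensity is
conserved. Parameters:

- `kappa = 30` grey levels (on the 0–255 scale): differences well below
  κ diffuse freely, well above are treated as edges and preserved. The
  value sits in the conventional range for 8-bit imagery.
- `lam = 0.2` per neighbor: explicit-scheme stability requires
  `lam ≤ 0.25`; 0.2 leaves a margin.
- `max_iter = 100`, `tol = 0.001`.

The stopping rule is statistical rather than a fixed iteration count.
After each step the multiplicative residual
`n_t = (A0 − A_t) / max(A_t, 1)` is formed (the one-grey-level floor
keeps the ratio defined on dark pixels) and its population excess
kurtosis `m4/m2² − 3` is computed. Under the speckle model, once the
filter has removed exactly the noise, the residual is unstructured and
approximately Gaussian, so iteration stops when `|k| ≤ tol`. When the
tolerance never triggers within `max_iter` steps — common when the
residual's kurtosis plateaus above zero — the fallback selects, among
visited iterates, the one minimizing `|ρ_A − ρ_M|`, where `ρ_A` is the
Pearson correlation of `A0` with the estimate and `ρ_M` with the
residual: the point where the estimate and the residual explain the
observation in closest balance. Both traces and the stop reason are
recorded in the result object. A constant input returns unchanged with
`stop_reason="degenerate"`.

Resizing to the 224×224 working size happens before denoising; the
pipeline's resize is bilinear with pixel-center coordinate mapping.

## Segmentation

Clustering runs on the 256-bin grey-level histogram, not on pixels:
levels are assigned to the nearest centroid by absolute intensity
distance (ties to the lower cluster index) and centroids are updated as
pixel-frequency-weighted means, so each iteration costs O(256·B) and
the procedure is fully deterministic. Default `B = 2` clusters
(lesion/background); B is configurable. Centroids are initialized
evenly spaced over the image's occurring intensity range — initializing
over the full 0–255 range strands clusters empty whenever an image
occupies a narrow band (e.g. a light lesion on light skin), which the
empty-cluster rule (keep the previous centroid) would never repair.
The lesion mask is the populated cluster with the lowest centroid;
a constant image raises a degenerate-input error, which the pipeline
driver converts into a full-image mask with a logged warning rather
than aborting a whole run.

## Features

**HOG.** Sobel gradients (3×3, reflected borders), unsigned orientation
folded to [0°, 180°), 9 bins of 20° with magnitude-weighted linear
interpolation between the two nearest bin centers (wrapping at 180°),
8×8-pixel cells, 2×2-cell blocks at one-cell stride, each 36-vector
normalized as `v/√(‖v‖² + k²)` with stabilizer `k = 1e−5`. On the fixed
64-wide × 128-tall input this yields 8×16 cells, 7×15 = 105 blocks and
a 3780-dimensional descriptor. Linear voting conserves total gradient
magnitude before normalization, which the tests exploit as an
invariant. HOG is computed on the masked, denoised grayscale image, so
it describes the lesion's border and interior structure.

**Deep descriptor.** The backbone follows the VGG19 layout (16 conv
layers in blocks of {2,2,4,4,4}, ReLU, 2×2 max pooling after each
block, FC head 4096 → 512 → 8 softmax) in plain numpy (im2col + BLAS
matmul, float32). The descriptor is tapped at the first FC layer after
its ReLU — 4096 values regardless of conv widths. Weights are
He-initialized from an explicit seed; with random weights the tap is a
deterministic nonlinear random projection, which preserves class
information in the input (intensity, shape, texture) without any
pretrained weights. The deep input is the resized RGB image (not the
masked one), so the two branches see complementary views. For small
problem sizes `BackboneSpec.scaled(f)` divides conv widths by `f` while
keeping depth, the 4096-wide tap and the head — the end-to-end tests
and the acceptance script use `scaled(8)`; the full-width layout is the
configuration default.

**Grad-CAM.** The class logit is differentiated analytically through
the FC head and the final max pooling (argmax unpooling) with respect
to the last conv block's ReLU output; channel weights are the spatial
means of those gradients, the weighted activation sum is rectified,
bilinearly upsampled and min-max normalized to [0, 1]. An all-zero
rectified map returns a uniform map flagged degenerate.

## Fusion, entropy selection, rebalancing

Fusion concatenates HOG (first) and deep blocks into 7876 values.
Each feature is scored by the Shannon entropy (log₂) of its training
values histogrammed into 256 equal-width bins spanning that feature's
training range; constant features score 0. The top 1186 features by
score are kept, ties broken toward the lower index. Scores are used
only ordinally, so any positive rescaling of the entropy would select
the same set. The selection, the per-feature standardization that
follows, and the rebalancing are all fit on training rows only and
applied unchanged to validation/test — validation/test row counts are
never altered.

SMOTE grows each minority class to the majority count with
`x_new = x + u·(x_nn − x)`, `u ~ U(0,1)`, `x_nn` one of the
`k_neighbors = 5` within-class nearest neighbors (capped below the
smallest class size); synthetic rows are flagged. Tomek links — mutual
1-NN pairs with different labels under Euclidean distance — are then
removed, both members, and recorded. Rebalancing operates in the
selected, standardized feature space: interpolating raw lesion images
is geometrically ill-defined, and feature-space resampling keeps the
procedure leakage-free.

## Classifier head and evaluation

The head is dense: 1186 → 512 (ReLU) → 8 softmax, trained with
minibatch RMSprop (decay 0.9, ε = 1e−8), learning rate 0.001, batch 32,
40 epochs, seeded shuffling; categorical cross-entropy (natural log,
probabilities clipped at 1e−12) is recorded per epoch, plus a mean
absolute deviation of probabilities from one-hot targets as a
diagnostic. A convolutional head was rejected: the input is a flat
selected vector whose coordinate order carries no spatial meaning.

The split is stratified 70:20:10 train:test:validation by seeded
largest-remainder apportionment within each class (per-class counts
within one sample of the target). Metrics derive from the confusion
matrix per class one-vs-rest (ACC, PREC, REC, F1; zero denominators
yield 0 with a degeneracy flag) and are macro-averaged; AUC is macro
one-vs-rest by rank statistic with midrank ties, excluding classes
absent from the evaluated split. One-way ANOVA (classical F and
upper-tail p) is provided for comparing accuracy collections across
models.

## Synthetic data generator

Each image is a darker elliptical lesion whose boundary radius is
perturbed by a unit-amplitude sum of low-order sinusoids (harmonics
2–4, random phases; harmonic 1 is excluded so the perturbation does not
merely translate the lesion), rendered on a smooth low-frequency
background texture (Gaussian-filtered noise, peak amplitude ≤ 10 grey
levels, so the denoiser has structure to preserve), with optional thin
dark Bézier hair strokes, then multiplied by unit-mean Gamma speckle
(default variance 0.05 — a fixture choice, as no noise statistics are
published for real archives) and tinted into RGB. The exact boolean
membership mask is returned alongside the image. Class identity is
encoded systematically: lesion mean intensity is spread evenly over
40–170 grey levels against a 220-level background (every class stays a
clearly darker, visible lesion under the speckle), and border
irregularity and texture amplitude cycle across classes. All
randomness flows through one explicit seed per call; identical inputs
give bit-identical outputs.

What the generator does **not** emulate: pigment networks, dots and
globules, multi-component color, vignetting, rulers/markers, specular
highlights, or inter-device color variation. Passing tests therefore
demonstrate that the pipeline's stages implement their contracts and
can learn intensity/shape-coded classes end to end — not that the
pipeline reaches any particular accuracy on real dermoscopy archives.

## Problem sizes and numerical choices

- End-to-end checks use 400 images (4 balanced classes of 100) rendered
  at 64 px and processed at 224 px with the width-scaled (1/8) backbone;
  this fits comfortably in single-CPU test runs. The imbalance
  (10:1) rebalancing contrast runs in an 8-D Gaussian feature space
  over 3 seeds; the end-to-end accuracy check runs once with a fixed
  seed.
- Population (biased) moments are used for kurtosis, matching the
  convention of the stopping rule; Pearson correlations are undefined
  for constant inputs and raise a degenerate-input error that callers
  handle explicitly.
- The diffusion step is stable for `lam ≤ 0.25`; conservation of total
  intensity under reflecting borders holds to machine precision and is
  tested at 1e−6 relative.
- k-means on the histogram stops when the largest centroid shift is
  ≤ 1e−6 or after 100 iterations; the within-cluster cost is
  non-increasing (tested).
- Backbone arithmetic is float32; batch extraction equals singleton
  extraction to float32 tolerance (summation order may differ across
  GEMM shapes).
- A seed fans out to stages via `seed·1000003 + crc32(stage)` mod 2³¹,
  so stages are independently reproducible.

## Known limitations

- The seeded-random backbone is a random-projection feature extractor,
  not a trained one; with pretrained weights the deep branch would be
  far stronger on real data. No pretrained mode ships because no
  offline weight source is bundled.
- The kurtosis stopping rule rarely fires exactly on natural-looking
  inputs (the residual's kurtosis can plateau above the tolerance); the
  correlation-balance fallback then governs, which is why both traces
  are recorded.
- Histogram k-means with B=2 fails on constant images (degenerate) and
  can mis-segment multi-modal backgrounds; no contour refinement or
  hole filling is attempted.
- SMOTE interpolation assumes local convexity of the class manifold in
  feature space; with very small minority classes (< 2 samples) it is
  undefined and raises.
- Tomek-link removal after SMOTE makes final class counts data-
  dependent; exact post-rebalancing counts are not a contract.
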