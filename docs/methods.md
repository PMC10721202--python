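# Methods

## Model and rationale

The package operationalizes a processing-based account of aesthetic
preference: the predictor of interest is not what an image contains but how
efficiently a visual system encodes it. Efficiency is measured as the
sparsity of the activation distribution of each layer of a convolutional
encoder — a sparse code concentrates activity in few units. The analysis
asks how much variance in mean opinion scores (MOS) of beauty this
layer-wise sparsity explains, on its own and relative to a conventional
feature-based account in which the activations themselves (PCA-reduced)
are the predictors.

## Sparsity metrics

Primary metric: the Gini index of the flattened post-ReLU activation
vector, computed from the ascending-sorted values as
G = Σᵢ (2i − n − 1) xᵢ / (n Σᵢ xᵢ) with 1-based i. The Gini index is used
because it satisfies the full set of inequity axioms (scale invariance,
transfer monotonicity, increase under added null values, cloning
invariance) that common alternatives such as kurtosis and the L1 norm
violate; all four axioms are property-tested. An O(n²) pairwise-difference
form, Σᵢⱼ|xᵢ − xⱼ| / (2n² x̄), is implemented separately as an independent
oracle and never used in production paths.

Alternate metric: Treves–Rolls sparseness. The classical activity ratio is
a = (mean x)² / (mean x²); the package reports S = 1 − a rather than the
(1 − a)/(1 − 1/n) normalization, and stamps the metric name into every
output table so the convention is auditable. The two conventions differ by
a factor that vanishes for large n (n ≥ 1024 for every measured layer of
the default encoder).

Degenerate inputs: an all-zero vector raises an error rather than
returning 0 or NaN — a layer that never fires has no defined code
inequity, and a silent sentinel would propagate into the regressions.
Vectors are rescaled by their maximum before accumulation (the metrics are
scale-invariant, so this is exact) to guard against under/overflow at
extreme magnitudes; sums use numpy's pairwise accumulation, adequate for
the 3.2-million-entry first convolution layer.

## Encoder

Two backends share one numpy feed-forward engine (3×3 same-padding
convolutions via strided windows + BLAS, 2×2 max pooling, dense layers;
float32 internally, float64 on export):

* **VGG16 adapter** — 13 convolution layers in five blocks
  (64/128/256/512/512 channels, feature maps 224→14 px) plus two 4096-unit
  fully connected layers, at 224×224 RGB input. Layer shapes are available
  without weights; inference requires a user-supplied `.npz` weight file
  (keys `conv{b}_{i}.weight` of shape (3,3,Cin,Cout), `fc{j}.weight` with
  row-major (H,W,C) input flattening). Weights are never downloaded
  implicitly. Input normalization is the ImageNet per-channel mean/std on
  the [0,1] scale.
* **Fixture network** — 3 convolution layers (8/12/16 channels) + one
  32-unit FC layer at 32×32 input, He-initialized from
  `numpy.random.default_rng(seed)`, zero biases, inputs scaled to [0,1].
  Same seed ⇒ bit-identical activations; used by all tests and
  simulations.

Measured activations are taken after ReLU and before pooling, flattened
row-major. Images are converted to RGB (grayscale replicated, alpha
dropped, logged as a warning) and resampled bilinearly straight to the
square input size; aspect ratio is not preserved, matching the simplest
deterministic choice. Inference has no stochastic elements, so repeated
extraction is bit-identical.

## Score scale

MOS from heterogeneous instruments are mapped affinely onto [0,5]:
5·(raw − min)/(max − min), with the bounds taken from the declared rating
instrument (e.g. a 1–7 Likert scale), never from the empirical min/max,
which would make rescaled scores dataset-dependent. The map is strictly
monotone and invertible; since R² is invariant to affine rescaling of the
response, the choice of [0,5] is cosmetic for the regressions.

## Feature reduction

One column-centered PCA per layer (per dataset); the retained count k is
the smallest number of leading components whose cumulative explained
variance reaches the target (default 0.80). Columns are centered but not
scaled; the PC scores are z-transformed afterwards, as are all sparsity
predictors (sample SD, n−1 denominator — stated because it changes values
at small n). Component signs are fixed by forcing the largest-magnitude
loading positive, otherwise PCA sign indeterminacy would break
reproducibility. The global 3-PC models slice the three leading components
of each layer regardless of k, so the full computed spectrum is kept in
memory (at most n−1 components).

## Regression battery

Five families: (1) univariate OLS per layer on sparsity; (2) ridge on all
layer sparsities (15 predictors for the default encoder); (3) ridge per
layer on its retained PCs; (4) global ridge on the first three PCs of
every layer (45 predictors); (5) global ridge on three PCs + sparsity per
layer (60 predictors).

Scoring: repeated k-fold cross-validation (defaults 10 folds × 100
repeats; scaled-down repeat counts are used in tests and the acceptance
script to keep runs fast). Held-out R² = 1 − SSE/SST with SST centered on
the test-fold mean; negative values are retained, not clipped. Fold
assignment is an explicit seeded permutation determined by
(seed, repeat_index), part of the module contract.

Ridge penalty: chosen from 50 log-spaced values in [1e−4, 1e4] (on
z-scored predictors) by 5-fold inner cross-validation nested inside each
outer training fold, so selection never touches test data; a single
global selection is available as an option. Ties on the inner error curve
go to the larger penalty. The solver computes the entire penalty path
from one SVD of the centered training design (intercept unpenalized);
it is cross-checked against an independent penalized solver in the test
suite. Reported coefficients come from a full-data fit at a full-data
selected penalty, since fold-wise coefficients are not uniquely defined;
for the per-layer report both the univariate coefficients and the
all-layer ridge coefficients are written, as either can be of interest.

Adjusted R² uses 1 − (1 − R²)(n − 1)/(n − p − 1) with n = total samples
and p = predictor count, applied to the CV-averaged R²; there is no
canonical adjustment under repeated CV, so the formula is recorded in the
run metadata.

Significance: seeded permutation of the response (default B = 10,000;
B = 99–199 in fast runs), p = (1 + #{permuted CV R² ≥ observed}) / (1 + B),
with the permuted statistic computed by exactly the same CV procedure as
the observed one. A parametric test is not used because the CV-averaged R²
has no standard null distribution. By default p-values are computed for
the per-layer univariate family only; multivariate-family permutation is
available behind a flag (each permutation repeats the full nested-CV fit,
which is costly).

Preprocessing leakage: the default mode fits z-scores and PCA on the full
dataset before cross-validation, replicating the common full-dataset
workflow; a leak-free mode (`preprocess="fold"` / `--no-leak`) refits both
inside every training fold via per-fold transformer objects. Both are
exposed because the difference is itself informative; at the sample sizes
tested the two agree closely for the sparsity families.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real images:

* **Activations**: Gamma(k, 1) draws per image and layer. Gamma is chosen
  because its population Gini has the closed form
  G(k) = Γ(k + ½)/(Γ(k + 1)√π), giving analytic anchors (k = 1, the
  exponential case, gives exactly ½) that are independent of the code
  under test; the Monte-Carlo checks use the pairwise oracle, keeping the
  verification path separate. The shape is drawn per image from a range
  (default 0.3–5.0, spanning Gini ≈ 0.23–0.78) as a mixture of a shared
  per-image latent factor and layer-independent noise; the mixture weight
  (default 0.5) induces the correlated layer sparsities seen in real
  encoders.
* **Scores**: y* = S·β + ε on the z-scored sparsity matrix, ε Gaussian.
  The noise SD can be set directly or derived from a target population R²
  via R² = Var(Sβ)/(Var(Sβ) + σ²). y* is mapped affinely (not clipped)
  onto [0,5]: clipping would distort the linear generative model that the
  parameter-recovery tests rely on. The map is recorded.
* **Fixture stimuli**: 32×32 "sparse_dots" (2–4 Gaussian blobs on black)
  vs "dense_noise" (full-field uniform noise); the two classes produce
  clearly different early-layer Gini through the fixture encoder, enabling
  an end-to-end recovery test from pixels to battery.

What passing tests show — and do not show: the synthetic generator
validates the machinery (metric correctness, CV calibration, parameter
recovery, determinism) under a known linear model with Gamma marginals.
Real image codes have spatial structure, inter-layer dependencies and
rating noise that no part of the generator emulates, so synthetic R²
values say nothing about the effect sizes to expect on real datasets.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down designs chosen to keep the
Monte-Carlo error comfortably inside the asserted bands: 1,000 random
vectors for oracle agreement (tolerance 1e−10), 10⁵ draws for the
distributional anchors (±0.01), n = 2000 / 15 layers / 2 CV repeats for
parameter recovery, 200 replicate datasets × B = 199 for permutation
calibration, and 200 images / 10 folds × 5 repeats for the end-to-end
fixture run. The package defaults (100 repeats, B = 10,000) remain the
recommended settings for real analyses.

Known limitations: the VGG16 forward pass is single-image, CPU-only numpy
(~0.6 s per image) — adequate for dataset sizes in the low thousands,
not for large-scale screening; no GPU path; activation caching is left to
the `extract` CLI's `.npz` cache; per-rater (non-MOS) modelling and
nonlinear models are out of scope.
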