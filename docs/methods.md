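# Methods

This note documents the models, the numerical choices behind them, and
what the synthetic validation does and does not establish.

## Preprocessing

**Skull stripping.** Threshold at half the Otsu cut of the positive
voxels (configurable: plain quantile), morphological opening with a ball
of radius `morph_radius` (default 2), keep the largest connected
component, dilate back, close, fill holes.  The halved Otsu threshold
keeps tissue that a strong bias field has darkened while still rejecting
the near-zero gap between brain and skull; the erosion step destroys the
thin bright skull shell so that the largest surviving component is the
solid brain.  On noisy phantoms the mask reaches Dice ≈ 0.93–0.96
against the generator's ground truth; at these grid sizes a single
boundary voxel layer is several percent of the volume, which bounds the
Dice achievable by any voxelized mask.

**Bias field correction.** The image is modelled as `I = B·C` with `B`
a smooth multiplicative field.  Working in the log domain, each
iteration (i) fits a piecewise-constant tissue structure to the current
corrected values with a small 1-D k-means (`bias_n_classes`, default 3,
quantile-initialised, deterministic), (ii) forms the residual
log-image − structure, (iii) low-pass filters the residual with a
normalized-convolution Gaussian (`smoothing_sigma_mm`, default 8 mm)
restricted to the positive-voxel mask, and (iv) accumulates it into the
log-field, re-centred to mean zero over the mask so the decomposition is
identified.  The recorded energy is the masked sum of squared residuals;
the loop stops when its relative change falls below `tol` **or** would
increase (in which case the previous state is kept), making the reported
trace non-increasing by construction.  This scheme is a deliberately
simple stand-in for heavier bias-correction machinery: a bias-free image
is an exact fixed point (the structure fit absorbs everything, the
residual vanishes), and on bias-dominated phantoms it removes 50–80 % of
the within-tissue coefficient of variation.  It does not model Rician
noise, partial volume or anatomy-correlated fields.

**Normalization and filtering.** Min–max rescaling to [0, 1] (a constant
image maps to zeros with a logged warning, and the operation is
idempotent); median filtering with reflect padding (borders never darken,
output values are order statistics of the input).  Step order is fixed:
strip → bias-correct → normalize → median.

## FPCM segmentation

Fuzzy memberships follow the standard c-means convention
`U_iC = 1/Σ_K (D_iC/D_iK)^{2/(M−1)}` (a voxel coinciding with a centre
takes membership 1 there, split evenly across coincident centres);
typicalities are `α_iC = 1/(1+(D_iC/η_C)^Q)`.  The objective sums
`U^M D² + α^Q D²` and centres update with the product weights
`α^Q U^M`.  Because the product-weighted centre update is not the exact
minimiser of this objective, monotonicity of the objective trace is
enforced by the stopping rule: if a sweep would raise the objective the
previous state is kept and iteration stops (treated as convergence).
In practice on separable data the trace decreases to convergence well
before this guard triggers.

`η_C` is calibrated once, after a short fuzzy-only warm-up (10 standard
FCM sweeps), as the membership-weighted mean squared distance within each
cluster (`K_scale` = 1), floored at 1e−6 to keep degenerate clusters
finite.  Cluster identities are fixed by sorting centres ascending, so on
T1-like contrast label 1/2/3 reads CSF/GM/WM.  Initialization is
deterministic by default (centres at the `(k+0.5)/c` quantiles, linear
interpolation); a seeded k-means++-style draw is available.  The default
`c = 3` targets the three tissue classes; `M = Q = 2`, `ε = 1e−5`.

On two-class phantoms (means 0.25/0.75, sd 0.03) the recovered centres
land within 0.02 of truth with ≥ 99 % label accuracy for at least 19 of
20 seeds.

## Atlas label transfer

Subject voxel indices are pushed through a user-supplied 4×4 affine into
atlas voxel coordinates and the atlas label is sampled by nearest
neighbour (labels are categorical; interpolation would invent labels).
Out-of-grid coordinates map to background.  The implementation is
vectorized but verified voxel-for-voxel against an explicit per-voxel
loop on small grids.  Deformable registration is out of scope; the affine
is an input.

## Feature descriptors

* **LBP** (P = 8, R = 1): neighbours ordered clockwise from the top-left
  corner with weights 2⁰…2⁷, the comparison is `s(x) = 1 iff x ≥ 0`, and
  only pixels whose full 8-neighbourhood lies inside the image contribute;
  the 256-bin histogram is normalized to sum 1.  The code is invariant
  under positive affine intensity maps.
* **Intensity moments**: mean, population (1/n) variance, and the raw
  third central moment — not standardized skewness.  The names m1/m2/m3
  follow the colour-moment convention even though MRI is single-channel.
* **Shape**: area is the pixel count; perimeter counts foreground pixels
  with at least one background 4-neighbour (the image border counts as
  background) — a boundary-pixel count, not an arc-length estimate, which
  matters when comparing compactness `perimeter²/area` values across
  implementations.  Eccentricity comes from the equivalent ellipse of the
  pixel-coordinate covariance with 1/12 added to both eigenvalues (each
  pixel treated as a unit square), so a one-pixel-wide line stays
  strictly below 1 and a single pixel is exactly 0.  Several regions in
  one mask reduce to the largest connected component.

Aggregation computes each region's descriptors on the central occupied
slice of its 3-D mask (configurable axis); a region absent on the
selected slices is recorded as a NaN sentinel and logged, never silently
imputed.

## DGWO feature selection

Positions live in `[0,1]^d` and are clipped after every update; masks are
`position > 0.5` (strict).  Fitness is `1 −` stratified 3-fold CV
accuracy of a nearest-centroid classifier on the selected columns,
standardized per training fold; folds are fixed once per table (seeded)
so all masks — including the exhaustive oracle's — are scored on
identical splits, and the empty mask scores 1.0.  The per-iteration
branch draws `R ~ U(0,1)`: grey-wolf siege step (fresh `r₁, r₂` per
agent, per leader and per component; `a = 2·l·r₁ − l` with `l` linear
2→0) or dipper-throated flying update (velocities persist; `c₃` linear
0.9→0.4, `c₄ = c₅ = 1.5`).  The swimming-bird update
(`BL ← BL_best − c₁·|c₂·BL_best − BL|`, `c₁` linear 2→0, `c₂ = 2r`) is
exposed for the pure-DTO mode.  Ties in best-ever fitness resolve to
fewer selected features, then lower agent index, making the whole search
a pure function of (seed, config, table).

On 10-feature planted-subset problems (2 informative at standardized mean
difference 4, 8 noise, n = 60), 10 agents × 30 iterations reaches within
0.02 error of the full 2¹⁰−1 enumeration optimum in ≥ 8 of 10 seeds.

## HAETN

Architecture (serial): per-slice depthwise-separable 3×3 convolution
(leaky rectifier, slope 0.1) → 2×2 max pool → CBAM (channel attention:
shared 2-layer MLP on global average- and max-pooled channel vectors,
summed, sigmoid; spatial attention: 3×3 convolution over the channelwise
average/max maps, sigmoid) → slice embedding = concatenated global
average and global max pooling, scaled by a constant calibrated once at
fit time so embeddings are O(1) → BiLSTM → + sinusoidal positional
encodings → one transformer encoder block
(`O = LayerNorm(X + FFN(Attention(X)))` as the single-residual form; a
conventional two-residual variant is available) → temporal attention
pooling `v = Σ_t α_t h_t` → dense (leaky rectifier, dropout 0.5) →
softmax.  An optional flag concatenates a handcrafted feature vector to
`v` before the dense head (off by default).  Defaults keep the published
configuration: 64 conv filters, 128 LSTM units (model width 256), 8
heads, 2048 FFN units, dropout 0.1/0.5, batch 32.

Design notes, in decreasing order of consequence:

* **Where the attention pooling sits.** A pooled context vector before
  the transformer would give the transformer a length-1 sequence, making
  it vacuous; the serial reading implemented here runs the transformer on
  the BiLSTM hidden sequence and applies the temporal-attention pooling
  to its output.  The BiLSTM+attention block is also usable (and tested)
  standalone.
* **Embedding scale, not LayerNorm.** Normalizing the slice embeddings
  with a mean-subtracting LayerNorm cancels exactly the common-mode
  response a bright focal structure induces across the few channels of a
  desk-scale encoder; a calibrated scalar preserves it while keeping the
  downstream LayerNorm stages well-conditioned.  The scalar is estimated
  from one forward pass of a probe batch and stored in the checkpoint.
* **Leaky rectifiers.** At reduced widths a plain ReLU leaves, for a
  substantial fraction of weight initializations, *every* encoder channel
  inactive on the discriminative region, zeroing its gradient permanently.
  The 0.1-slope leaky variant removes that failure mode; at published
  widths the choice is immaterial.
* **Average + max slice embedding.** Pure average pooling dilutes a
  focal structure by the slice area; the max component routes gradient
  directly to the responsible pixels and speeds up learning of focal
  signals considerably.
* **Optimizer.** SGD with momentum 0.9, cross-entropy loss,
  global-gradient-norm clipping (default 5.0), all randomness from one
  seeded generator: same-seed training is bitwise reproducible
  (single-threaded numpy).  A seeded restart-on-plateau policy
  (`max_restarts` = 3) reinitializes from the next derived seed if
  training accuracy is still below 0.65 after 5 epochs — small networks
  occasionally start in a basin whose escape would take several times the
  epoch budget; restarts are cheap and deterministic.
* **Grad-CAM.** The class log-probability (not the raw logit, whose
  shared offset the softmax ignores) is backpropagated to the CBAM
  output; channels are combined by the *magnitude* of their
  spatially-pooled gradient, since the normalization layers between the
  encoder and the head make the raw gradient sign gauge-dependent, while
  the rectified activations carry the localization.  Maps are rectified,
  normalized per slice to [0, 1] (all-zero maps stay zero with a
  warning), and bilinearly upsampled to the input slice size.

The network, training loop and Grad-CAM all run on a small in-repo
reverse-mode autodiff engine over numpy arrays (`fasf_tle.autodiff`),
written for clarity at desk scale; its gradients are verified against
central finite differences for every layer type.

## Evaluation

Confusion counts take class 1 (TLE) as positive.  Ratios with zero
denominators are reported as NaN with a warning — never silently 0 — so
aggregates cannot be corrupted by degenerate folds.  ROC curves and
trapezoidal AUC come from scikit-learn (ties grouped), and AUC is checked
against a concordant-pair (Mann–Whitney) oracle in the tests.  K-fold
evaluation is stratified with a fixed seed and trains a fresh model per
fold; the report layout is one row per fold plus mean ± sd per metric.

## Synthetic data and what passing means

The phantom is an ellipsoidal brain with a small dark CSF-like core
(radius fraction 0.3 of the brain), a bright WM-like middle band (to
0.75) and a GM-like outer band — means 0.2/0.5/0.8, sd 0.03 — separated
from a bright skull shell (intensity 0.9, ~2 voxels thick) by a ~3-voxel
dark gap; corrupted by a smooth multiplicative field `exp(g)` (Gaussian-
filtered white noise, default amplitude 0.2, smoothness 12 voxels),
salt-and-pepper impulses (default 2 %) and optional Gaussian noise.  The
toy atlas partitions the brain into equal-count slabs (region 1 flagged
temporal-lobe-like).  Feature tables plant informative class-conditional
normal columns at a chosen standardized mean difference among independent
noise columns, with a recorded shuffle.  Slice datasets plant a bright
Gaussian blob in a fixed quadrant of the two central slices of class-1
sequences (contrast 0.8 against noise sd 0.05 on 16×16×6 sequences, 20
per class).

These generators produce separable, stationary, geometry-simplified
data.  Passing the suite demonstrates that every formula is implemented
as printed, every stage recovers planted ground truth under its stated
conditions, and the whole pipeline runs deterministically end to end.
It does not demonstrate clinical performance: real MRI brings Rician
noise, partial-volume mixing, anatomy-correlated bias, registration
error and far weaker class signals, none of which the phantoms model.

## Problem sizes

Defaults used by the test suite and the acceptance script: phantoms
48×48×24 or 64×64×32; FPCM recovery on 3 000-voxel 1-D problems over 20
seeds; DGWO on 60 × 10 tables against the 1 023-mask enumeration over 10
seeds; HAETN at reduced width (8 conv filters, 8 LSTM units, 2 heads,
32 FFN units, dense 16, learning rate 0.1, gradient-norm clip 0.3) on 40
sequences for 15 epochs, with 3-fold cross-validation.  These sizes were
chosen so the full validation runs in about a minute on one CPU while
leaving every recovery criterion non-trivial.
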