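# Methods

This note documents the models and procedures implemented in `mitodet`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open and a choice had to be made.

## Stain model and normalization

Transmitted-light H&E images are treated with the Beer–Lambert model:
per-pixel optical density `OD = -log10((I + ε)/I0)` with background
intensity `I0 = 255` per channel and `ε = 1/255` guarding `log(0)`. Stains
mix approximately linearly in OD space, so a tile is modeled as
`OD ≈ Cᵀ M`, where `M` is a 2×3 matrix of unit-norm stain vectors (rows:
hematoxylin, eosin) and `C` the per-pixel concentrations.

The data-driven stain estimator is the robust angular-extremes method:
OD pixels above a transparency floor (magnitude > 0.15) are projected onto
their top-2 principal plane; the 1st/99th percentile directions of the
projected angle are taken as the two stain vectors; the row with the
larger red-channel OD is labeled hematoxylin (hematoxylin absorbs red,
eosin barely does). Concentration scales are per-stain 99th percentiles,
robust to outliers. When no stain plane is identifiable (near-blank or
grayscale input) the estimator raises a degenerate-reference error, or —
when configured — falls back to the published standard H&E vectors
(`[0.65, 0.70, 0.29]` / `[0.07, 0.99, 0.11]`, unit-normalized).

Normalization solves `C` for the source tile by least squares (clipped
non-negative), rescales each stain so its 99th-percentile concentration
matches the reference profile's, and re-renders through the reference
matrix. A stain whose source scale is below 0.05 is considered absent and
passed through unrescaled, so all-background tiles survive unchanged.
Known limitation: any OD component orthogonal to the two-stain plane
(e.g. brown pigments) is projected away.

Preprocessing resizes to 227×227 (the detector's published input size)
with bilinear anti-aliased interpolation, applies a per-channel 3×3 median
filter (kernel size is a convention; none is published), and resizes masks
nearest-neighbor so they stay binary. Dataset splitting uses seeded
largest-remainder allocation, stratified per class, which makes partitions
disjoint, exhaustive and within ±1 item per class of the requested
fractions by construction.

## The 150-slot feature bank

The registry is versioned (`default-1.0`) so a selection result can cite
the exact slot composition: 86 texture + 42 shape + 22 color, giving
category shares 57.3/28/14.7% — inside the 50–60/25–30/10–15% bands
reported for selected mitosis descriptors.

* **LDP (56 slots).** Per interior pixel the eight Kirsch compass masks
  are correlated with the 3×3 neighborhood; the code is the *set* of the
  k = 3 largest absolute responses, ranked into one of C(8,3) = 56 bins.
  Ties break toward the lowest mask index (deterministic; a constant image
  lands entirely in bin 0). The histogram is normalized to sum 1.
* **LFP (30 slots).** No standard definition of "local frequency
  patterns" exists, so the operator is declared: a Gabor bank of 5 radial
  frequencies (geometric from 0.08 to 0.4 cycles/px, kernels kept local)
  × 6 orientations; for each filter the fraction of pixels whose response
  magnitude exceeds its own 9×9 local mean plus a small margin (1e-6 on
  unit-scaled images) is recorded. Rates live in [0, 1]; a constant image
  scores 0 everywhere.
* **Shape (42 slots).** Area, perimeter, eccentricity, circularity
  (4πA/P², the contour-length perimeter estimator) and solidity per
  8-connected component, aggregated with mean/sd/min/max/median/IQR/
  skewness/sum, plus component count and foreground fraction. An empty
  mask yields the zero vector. Rasterization limits the fidelity of the
  geometric slots — a radius-20 disk measures circularity ≈ 0.91 and
  solidity ≈ 0.96 because the discrete convex hull slightly exceeds the
  pixel set; tests assert tolerances accordingly. When a tile has no mask,
  foreground is estimated by Otsu thresholding the hematoxylin
  concentration channel.
* **Color (22 slots).** Mean/sd of R, G, B, H, S, V (hue treated
  circularly, undefined where saturation is zero), an 8-bin mass-normalized
  hue histogram (undefined hue assigned to bin 0 by convention), grayscale
  Shannon entropy (bits, 256-bin), and the Hasler–Süsstrunk colorfulness
  index on unit-scaled channels.

## Metaheuristic core

Both optimizers run on box-bounded continuous spaces with greedy
acceptance, as minimizers; maximization wraps the objective as
`1 - value`. Non-finite objective values are treated as +∞ and never
stored. Reproducibility is exact: one `numpy` generator drives every draw.

**Jellyfish search.** Chaotic initialization iterates the logistic map
`y ← 4y(1−y)` from seed `q0` (the printed recurrence is internally
inconsistent; the standard map it describes is used), assigning successive
iterates across agents and dimensions, then mapping affinely into the
bounds; `q0` must avoid the map's fixed/periodic points {0, ¼, ½, ¾, 1}.
Per agent and iteration one time-control value
`TCF = |(1 − t/t_max)(2·rand − 1)|` is drawn and reused for both gates:
`TCF ≥ κ` (κ = 0.5) triggers the ocean-current move
`Y′ = Y + R⊙(Y* − 3·R′⊙λ)` with `λ` the population mean and per-dimension
fresh draws; otherwise a uniform draw above `1 − TCF` gives the passive
type-A drift (`0.1`-scaled span), else the active type-B move toward a
fitter random partner / away from a less fit one. Out-of-bounds
coordinates wrap to the opposite limit (the printed second branch of the
wrap rule has a sign error; `Y < LB` is implemented), then clip any
residual overshoot.

**Walrus optimization.** Three phases, cycled one per iteration when
driven by the hybrid loop: feeding `Z′ = Z + rand⊙(W* − RI⊙Z)` with
`RI ∈ {1,2}`; migration toward a fitter random partner or away from a less
fit one; and escape, sampling a local neighborhood. As printed, the
escape-phase "local" bounds equal the global bounds, which makes the phase
a global random restart; both behaviors are selectable
(`neighborhood_mode="as_printed"`), and the default `"shrinking"` mode
uses a neighborhood of span `(UB−LB)/t` centered on zero offset, matching
the algorithm family's intent of tightening exploitation over time. Walrus
moves clamp to bounds (no boundary rule is published for them).

Sanity benchmark: on the 5-D sphere with 30 agents and 200 alternating
jellyfish/walrus iterations, all tested seeds reach best fitness far below
1e-2, and greedy acceptance makes the best-fitness history monotone by
construction.

## Hybrid wrapper feature selection

Subsets are encoded as positions in [0,1]^d, binarized at 0.5 (a
coordinate exactly at threshold selects its feature). Fitness is the
pooled stratified k-fold (default 3) cross-validated F1 of a fast
ridge-regularized linear discriminant — class means plus pooled
within-class covariance with an isotropic ridge of 1e-3 × mean variance,
prior-corrected midpoint threshold — on the z-scored selected columns. The
evaluator inside a wrapper loop must be cheap; it is hand-rolled because
it runs thousands of times per selection and is swappable via the
`classifier` argument. An empty subset scores 0. Fitness values are cached
by mask.

Each iteration every agent builds a jellyfish candidate and a walrus
candidate (phases cycling feed→migrate→escape); with probability 0.8
(published crossover rate) the two recombine by per-dimension uniform
crossover, otherwise the fitter is taken; with probability 0.2 (published
mutation rate) one uniformly chosen dimension is resampled; greedy
acceptance against the incumbent closes the iteration. The run stops at
the iteration cap or after 15 iterations without a best improvement. Ties
between equal-fitness masks prefer fewer features, then the
lexicographically smaller mask. The published "top 50%" rule and the
reported 35–50 selected-feature range conflict (50% of 150 is 75); neither
is enforced — both are emitted as informational diagnostics in the
selection report.

## The CDL detector

A VGG-16-style backbone — thirteen 3×3 same-padded convolutions in five
pooled blocks (64/128/256/512/512 channels at full width) — converted to a
fully convolutional network: the three FC layers become 1×1 convolutions
(4096 channels at full width; the final classification layer is replaced
by a 1-channel mitosis score head). Three skip connections project the
pool4/pool3/pool2 feature maps through 1×1 convolutions (initialized near
zero so training starts from the coarse prediction) and are added into a
staged transposed-convolution upsampling path (×2, ×2, ×2, then ×4, each
kernel = stride, initialized to nearest-neighbor interpolation and
trainable). Inputs whose side is not a multiple of 32 are reflect-padded
up and the output cropped back, so the probability map always matches the
input spatially — this realizes the upsample-and-crop bookkeeping without
per-stage crop offsets.

`width_scale` multiplies channel counts only, never the layer structure,
so the full 13-conv architecture is trainable at desk scale; the published
width is `width_scale = 1`. The implementation is a compact CPU NumPy
layer library with explicit forward/backward passes (im2col convolution,
2×2 max pooling, non-overlapping transposed convolution, inverted dropout)
verified against float64 finite differences; an Adam optimizer supports
two learning-rate groups so transferred layers (the first two
convolutions, when a source weight file is provided; nothing is ever
downloaded) train at 1e-5 while new layers train at 1e-3 — the two
published learning rates, reconciled as a two-group schedule.

Training minimizes focal loss, `mean(-α(1-p_t)^γ log p_t)` with α = 0.25,
γ = 2 and probabilities clamped at 1e-7; at γ = 0, α = 1 it is exactly
mean binary cross-entropy. α is a pure scale here (the published
description names the loss but no formula); the (1−p_t)^γ modulation is
what counteracts the ~1% mitotic-pixel prevalence. L2 (1e-4) applies to
weight matrices, dropout 0.3 to the FC-equivalent layers, flips/brightness
(±20 levels)/contrast (0.8–1.2) augmentation to training batches.
Validation loss drives both plateau LR halving (relative threshold 1e-3,
patience 3 epochs, configurable) and early stopping (strict improvement,
patience 5 by default, 100-epoch cap).

Post-processing thresholds the probability map at 0.5, labels 8-connected
components, drops those under 10 px, and reports centroid/area/mean score
per detection. Object-level scoring uses centroid-within-mask matching:
a detection is a true positive when its centroid falls inside a
not-yet-matched ground-truth component.

The selected handcrafted features and the segmentation network are kept as
two composable paths (feature-table classification and dense
segmentation); no fusion between them is claimed or implemented, since no
fusion mechanism is published.

## Evaluation metrics

All eleven metrics derive from one 2×2 tally: sensitivity, specificity,
accuracy, F-measure, CSI = TP/(TP+FN+FP), balanced accuracy
(Sen+Spec)/2, Fowlkes–Mallows √(precision·recall), markedness
(precision + NPV − 1), negative likelihood ratio (1−Sen)/Spec, FPR =
1−Spec, FNR = 1−Sen. The identity-derived forms are authoritative: the
published comparison table's FPR/FNR rows are not exactly 1−Spec/1−Sen,
and its MK values (~0.03–0.06, described as lower-is-better) are
inconsistent with any standard markedness definition; the implementation
documents rather than reverse-engineers this. Zero denominators yield a
sentinel 0 plus a `degenerate` flag list so reports always serialize.

## Synthetic data

The tile generator is the package's test substrate and defines its study
conditions. It renders a smooth eosin-tinted stromal field, elliptical
hematoxylin-stained nuclei (radius 5% of the field width — a ~10 µm
nucleus in a 40× tile), and mitotic figures as star-convex radially
perturbed shapes with markedly higher hematoxylin concentration (darker,
irregular chromatin), composes everything through the same OD stain model
the normalization module inverts — with per-tile angular jitter of the
stain vectors — and adds Gaussian sensor noise. The mask marks exactly
the mitotic footprints, kept pairwise disjoint by construction, so mask
component counts are exact ground truth. `easy` difficulty gives high
mitotic/nuclear contrast (concentrations 1.35 vs 0.55) and clear
separation; `hard` reduces contrast (0.95 vs 0.65) and packs objects
tighter. A paired-generation helper renders the *same* scene under two
independent stain draws — the controlled setting for normalization tests.

What the generator does **not** emulate: out-of-focus blur, tissue folds,
staining artifacts, apoptotic mimics, overlapping chromatin textures, and
the full morphological diversity of real mitotic phases. Passing tests
therefore demonstrate internal correctness and desk-scale learnability,
not clinical performance; the published dataset-level accuracies are out
of reach by design and are not claimed.

The table generator draws labeled vectors with a known informative subset
(standardized mean shift `effect_size`, default 2.0 ⇒ per-column AUC
Φ(2/√2) ≈ 0.92), exact class allocation, and optionally equicorrelated
nuisance columns; it is the ground truth for selector recovery
experiments.

## Problem sizes and numerical choices

Experiments are sized for a single CPU: selector recovery runs use
population 30 × 50 iterations (n = 300, d = 150); the exhaustive oracle
runs at d = 12 (4096 subsets); the detector smoke experiment trains the
quarter-width network on 40 easy 96-px tiles (8 validation, 20 held-out
test) for up to 25 epochs with early-stop patience 10 — at this scale the
focal-loss warmup plateau routinely exceeds 5 epochs with a small
validation set, so the desk-scale schedule uses the larger patience while
the production defaults remain patience 5 and 100 epochs. Forward/backward
passes are float32 (losses and gradients accumulate in float64 at the loss
layer); determinism is exact per platform but bitwise results may differ
across BLAS builds. Degenerate inputs (empty masks, blank tiles,
single-class labels, non-finite objective values) raise typed errors or
return documented sentinels rather than propagating NaNs.
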