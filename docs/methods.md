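# Methods

## Problem and approach

Mohs micrographic surgery removes nonmelanoma skin cancer in stages, with
the surgeon reading H&E frozen sections intraoperatively. `mohsmap`
implements a tile-based pipeline that localizes tumor in single microscope
field-of-view images: the image is split into fixed-size square tiles, a
convolutional classifier scores each tile for tumor content, and
overlapping sliding-window predictions are assembled into a per-cell
probability (saliency) map that is scored against expert segmentation
masks at the prediction-grid level.

The pipeline has two training regimes:

* **Fully supervised (FSL).** Tiles from annotated tumor images are
  labeled *positive* when tumor occupies ≥ 10 % of the tile area
  (inclusive) and *control* otherwise; every tile of other-diagnosis
  images (the other tumor type, actinic-keratosis-like distractors,
  normal skin) can be added as extra controls.
* **Weakly supervised (WSL).** No masks: every tile of a tumor-diagnosis
  image is weak-labeled positive and every control-image tile control.
  A first-stage classifier is trained on these noisy labels; the second
  stage keeps only weak-positive tiles whose stage-1 inferred tumor
  probability reaches the filtering threshold *t* (default 0.5,
  inclusive), never touches control tiles, and retrains from a fresh
  initialization. Exactly two stages; no iterative self-training.

## Classifier

The architecture contract is a convolutional feature extractor feeding
exactly three dense layers and a final softmax, trained with categorical
cross-entropy. The built-in backbone (`small`) is a compact two-block
convolutional network implemented directly on numpy (valid 3×3
convolutions, ReLU, 2×2 max-pooling, dense widths 256–64–16 by default),
with exact backprop verified against finite differences; tiles are
resampled to a 32 px input side. External pretrained backbones can be
registered through `register_backbone`; none are bundled and nothing is
downloaded.

Training uses Adam (default learning rate 1e-3, batch 32), label-preserving
augmentation (flips, right-angle rotations, brightness/color jitter bounded
by the configured deltas), early stopping on a *patient-grouped* validation
split (patience 10, best weights restored) and a hard cap of 200 epochs.
The loss applies inverse-frequency class weights by default
(`TrainConfig.class_balance`). This matters for WSL stage 1: background
tiles occur under both labels, and with an unbalanced loss their predicted
probability converges to the positive-pool prior (≈ 0.65 at the demo's
2.5 : 1 imbalance), so the *t* = 0.5 filter would keep every tile. With
balancing, ambiguous background converges below 0.5 and filtering behaves
as intended; clean tumor tiles are unaffected.

## Saliency maps

Inference tiles the image on an edge-snapped grid (regular stride, plus one
extra origin per axis at `dim − tile_size` so border content is always
covered; windows are half-open, coordinates 0-based row-major). The
prediction grid consists of stride-sized cells anchored at the origin, the
last row/column truncated at the border. A tile window's tumor probability
is credited to every cell that lies fully inside it; overlapping
contributions are combined by arithmetic mean (max available). The default
inference stride is half the tile size — overlap is the point of the
technique. Cross-magnification inference rescales images bicubically by the
magnification ratio (40× → 100× is ×2.5) and masks by nearest-neighbor to
preserve binarity.

## Evaluation

Ground truth is reshaped to the prediction grid: each cell's tumor fraction
is the mean mask value over its pixel block, binarized at a majority (0.5)
threshold. Metrics are computed on flattened grid cells:

* **AUPRC** — step-wise average precision over all thresholds (tie groups
  collapse to one operating point); the primary metric.
* **AUROC** — rank probability that a positive cell outscores a negative
  one, ties counted ½.
* **Highest Dice** — max over a threshold sweep (all distinct map values
  plus {0, 1}; 101 evenly spaced values for very large grids); the smallest
  achieving threshold is reported.
* **FEP** — AUPRC divided by the positive-cell proportion: the precision
  gain over a random locator.

An image is evaluation-eligible when ≥ 10 % of its grid cells are non-tumor
(inclusive; computed from cell counts so the boundary is exact in floating
point) and at least one cell is tumor — AP is undefined otherwise. An
optional pixel-level mode upsamples the map instead of downsampling the
mask; grid mode is the default.

## Validation statistics

* **Patient-level LOOCV**: one fold per eligible patient (annotated, with
  ≥ 1 metric-eligible image), folds sorted by patient id; training
  patients are all other annotated patients, so no patient's images ever
  straddle the split.
* **Bootstrap**: percentile CIs from 10,000 ordinary resamples of per-image
  metric values (the across-image median is the default statistic);
  deterministic given a seed.
* **Paired Wilcoxon**: two-sided signed-rank on per-image differences,
  zeros dropped for the statistic (ties mid-ranked), exact null for small
  samples (n ≤ 25, distinct magnitudes) and the normal approximation with
  continuity correction otherwise; the reported median difference includes
  zero pairs. Significance is declared at α = 0.01.
* **Fleiss' kappa**: each rater's mask is tiled into 50 × 50 px blocks
  (edge-snapped) and binarized at ≥ 5 % tumor fraction (inclusive); items
  are tiles pooled across images (per-image averaging available),
  categories {tumor, non-tumor}.

## Synthetic data

The study's clinical images are not distributable, so a generator emulates
their structure: an eosin-pink colored-noise stroma with sparse dark
nuclei, and tumor regions — unions of random analytic ellipses — re-tinted
toward the tumor hue and stamped with a dense nucleus field (basaloid
purple for BCC-like, keratinizing orange-brown for SCC-like). A single
`separability` parameter in [0, 1] interpolates both the tint contrast and
the nucleus density: at 0 the tumor region is rendered by the untouched
background process (identically distributed), at 1 the color/texture
statistics are well separated. The mask is exactly the analytic geometry
(a pixel is positive iff its center falls inside a blob; no partial
coverage). Distractor kinds: `other_tumor`, `follicle_rings`,
`inflammation_speckle`, `plain`. All randomness flows from one integer
seed through counter-based per-image substreams, so outputs are
order-independent and bit-reproducible.

Cohorts assign each patient a single diagnosis drawn from a class mix and
place patients whole into development/validation splits, stratified by
diagnosis so both splits contain each class whenever counts allow.

What the generator does **not** emulate: staining and freezing artifacts,
air bubbles, tissue folds, out-of-focus regions, infiltrative growth
patterns, or the long-tailed tumor-area distribution of real sections.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under controlled separability — not clinical-grade accuracy on
real frozen sections.

## Problem sizes and scale choices

The demo experiment uses 12 patients × 4 images at 448 × 448 px
(separability 0.9, class mix 2/3 BCC-like, 1/6 SCC-like, 1/6 normal),
about one-quarter the linear size of the production 1600 × 1200 images.
The demo tile size (64 px) and inference stride (32 px) are scaled by the
same factor to preserve the production tile-to-image ratio of ≈ 7; with
224 px tiles on a 448 px image a single window spans half the image, so
grid cells adjacent to tumor inherit near-1 probabilities from any window
containing tumor and AUPRC saturates well below its attainable value
regardless of classifier quality. Production defaults (224 px tiles,
112 px inference stride, full-size images) remain the package defaults.
Coverage simulations for the bootstrap use 500 replicate datasets of
n = 60 with 1,000 resamples each.

## Numerical choices and degenerate inputs

Float64 throughout the network for exact, reproducible gradients; softmax
is computed with max-subtraction; cross-entropy clips probabilities at
1e-12. Max-pool gradients split evenly across tied maxima. Early stopping
requires strict improvement (> 1e-12) of the validation loss. Empty
filtered tile sets, single-class training data, all-zero paired
differences, single-category agreement tables, and metric calls without
positives all raise typed errors rather than returning silent defaults.

## Known limitations

The built-in backbone is deliberately small and CPU-friendly; it is not a
substitute for a fine-tuned production feature extractor on real imagery.
Grid-level metrics understate boundary localization error below the cell
size. The WSL enrichment behavior depends on the presence of control
images; with no controls the stage-1 model cannot separate background
from tumor texture.
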