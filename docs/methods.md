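# Methods

## Problem and approach

`loiseg` trains a single-cell instance segmentation model without
per-cell mask annotations.  The training signal consists of two weak
annotations that can be produced programmably from routine experimental
data:

* an **image-level segmentation** — one binary mask separating all
  cell pixels from background (e.g. from thresholding a fluorescence
  channel or an interactive graph-cut tool), and
* **locations of interest (LOIs)** — one approximate point per cell
  (e.g. detected in a DAPI nucleus channel), carrying position but no
  shape information.

The model outputs a ranked list of per-cell soft masks that may
overlap; no watershed or other post-processing is applied.

## Architecture

Three fully convolutional sub-networks run at inference time:

1. **Backbone** — a small encoder/decoder with U-Net-style skip
   connections producing a feature pyramid at strides 1, 2 and 4
   (default widths 16/32/64; ~1.4 × 10^5 parameters).  Inputs are
   normalized per channel to the 1st–99.8th percentile range and
   reflect-padded to a multiple of the maximum stride.
2. **Location proposal network (LPN)** — a keypoint head on the
   stride-4 level predicting a per-cell objectness heatmap plus a
   two-channel sub-stride offset.  Deliberately *no* size or box
   regression exists anywhere: LOIs carry no extent information, and
   the whole pipeline is box-free.
3. **Segmentation head** — runs once per proposed LOI on a
   `crop_size` window (default 32 px) of the stride-1 features.  The
   window is concatenated with a **positional encoding** of each pixel
   relative to the LOI — channels (Δrow, Δcol, radius)/crop_size,
   linearly projected to `encode_dim` (default 4) channels.  This
   encoding is what breaks the translational invariance of the
   convolutional features; without it every LOI on the same image
   would produce the identical patch (a property covered by a test).

A fourth network, the **auxnet**, exists only during training: four
stride-1 3×3 convolutions (receptive field 9 px, structurally bounded
by `auxnet_fov` = 13 px) predicting per-pixel cell-boundary
probability.  Its deliberately small field of view forces it to learn
local edge evidence rather than whole-cell shape, complementing the
large-FOV main network.

## Losses

**LPN.** Targets are rendered as the pointwise max of unit-height
Gaussians (`heatmap_sigma`, default 3 px) at each annotated LOI, with
the containing grid cell set to exactly 1.  The score map trains with a
penalty-reduced focal binary cross-entropy (positives
`-(1-p)^2 log p`; negatives weighted `(1-t)^4`), offsets with an L1
penalty at positive cells only.

**Full supervision.** Each soft-mask crop is paired with the
ground-truth instance whose (jittered) centroid anchored it, under
mean per-pixel binary cross-entropy.

**Weak supervision.** With per-instance probability frames `p_k` placed
into the image frame (zero outside each crop):

* *image consistency* — `q(x) = 1 - Π_k (1 - p_k(x))`, the
  probabilistic union, scored against the image-level mask by
  per-pixel binary cross-entropy;
* *overlap* — `Σ_x Σ_{j<k} p_j(x) p_k(x) / Σ_x q(x)`, penalizing
  doubly-claimed pixels, normalized by the total predicted foreground
  (defined 0 when nothing is predicted).

Both terms vanish exactly when the predictions hard-tile the mask
without overlap, and each strictly increases when a prediction claims
a background pixel or an instance is duplicated.

**Auxnet co-training** (two stop-gradient terms, active after a warm-up
of 10% of training so the pseudo-labels are meaningful):

* *auxnet fit* — binary cross-entropy between the auxnet map and
  pseudo-boundaries of the *detached* main-network predictions
  (3×3 morphological gradient of each thresholded mask, unioned);
* *boundary consistency* — by default a one-sided **edge
  suppression** term: the total soft-edge magnitude of the
  predictions (2×central differences, so a unit step saturates at 1,
  clipped to [0, 1]) is penalized wherever the *detached* auxnet map
  sees no boundary, restricted to a 3-px dilation of the image mask.
  Mask borders are thus free to sit on the seams the auxnet finds but
  pay for running through boundary-free interior.  A symmetric
  mean-squared-difference variant is selectable
  (`ModelConfig.boundary_loss = "mse"`); in practice it over-sharpens
  by demanding full-strength edge rings from uncertain masks.

Gradient isolation is a tested contract: the fit term moves only
auxnet weights, the consistency term only main-network weights.  All
logarithms are clamped at 1e-6.  Term weights default to 1.0 each.

## Training protocol

He initialization and ADAM (default lr 2 × 10⁻³) throughout.  One
image per step; augmentation by random flips and 90° rotations.  The
segmentation head is teacher-forced from annotated LOIs jittered by
±2 px (uniform), while the LPN trains in parallel from its own loss —
this decoupling keeps small-scale training stable.  When a validation
set is provided, the weights with the highest validation AP at IOU 0.5
are kept, and stochastic benchmark runs may select the better of two
seeded reruns by the same criterion.

## Synthetic scenes

The generator emulates the dense-culture regime the method targets:
rotated filled ellipses (radius 6–11 px, axis ratio up to 1.8) with
low-frequency interior texture, a configurable fraction of cells
allowed to touch or overlap neighbors, a correlated nucleus channel
(smaller bright ellipse per cell, center jittered by 2 px), additive
Gaussian noise, and LOI lists corrupted at configurable false-positive
/ false-negative rates (default 1.5% each, the few-percent error
regime a simple blob detector achieves on real nucleus stains).
Optional knobs narrow the per-cell brightness spread and add a darker
1-px membrane seam along every cell border, producing scenes whose
cell-cell boundaries are ambiguous enough that boundary co-training
matters.  Instances are stored as independent, possibly overlapping
masks; the image-level mask is always their exact union.

One integer seed drives placement, shapes, noise and corruption
through independent derived streams, so scenes are bit-reproducible.

What the generator does *not* model: imaging point-spread functions,
modality-specific contrast (phase rings, halo artifacts), irregular
non-elliptical cell shapes, uneven illumination, or 3-D structure.
Passing benchmarks on these scenes demonstrates that the training
machinery works as designed, not that a given accuracy will transfer
to any particular real modality.

## LOI machine annotation

Nucleus LOIs are detected as 4-connected local maxima of a
difference-of-Gaussian filter with σ = 4.2 and 5 px.  Plateaus of
equal value are collapsed to their centroid so ties never yield
duplicate detections; maxima near the border are kept (edge nuclei are
real cells).  The default peak threshold is a robust noise floor,
3 × 1.4826 × MAD of the DoG response, which keeps false positives and
negatives in the few-percent range on the synthetic nucleus channel.

## Evaluation

* **AP** = `(1/C) Σ_k P(k) T(k)` over the score-ranked detection list,
  with greedy rank-order matching and the no-double-match rule; a
  detection is positive iff its best unmatched ground-truth IOU meets
  the threshold.  mAP averages IOU thresholds 0.50–0.95 (step 0.05).
  Detections are pooled across images by score before ranking
  (the convention of the AP literature).  Empty conventions: C = 0
  with no detections → 1; C = 0 with detections → 0.
* **AJI** — each ground-truth cell greedily claims its best-Jaccard
  unused prediction (ties to the lowest prediction id; zero-overlap
  cells contribute their area to the denominator), and unmatched
  predictions count against the denominator.  Each prediction is used
  at most once; a flag exposes the non-exclusive variant.  For
  overlapping instance lists the flattened label partition is used.
* **Detection precision/recall/F1** at IOU 0.6.

Flattening for label-map export assigns contested pixels to the
highest soft probability (ties to the higher-scoring instance) and
never labels a pixel outside the union of hard masks.

## Desk-scale benchmark sizes

All shipped benchmarks run on one CPU with no pretrained weights; the
default model totals ≈2 × 10⁵ parameters.  The test-suite benchmark
(end-to-end weak training and the auxnet ablation) uses 32 training
scenes of 96 × 96 px in the dense boundary-ambiguous regime — 9–13
cells, 70% of cells exempt from the spacing constraint, narrow
per-cell intensity spread (0.62–0.74), 1-px membrane seams
(`rim_shade` 0.22), noise σ 0.06 — for 15 epochs, evaluated on 16
held-out scenes.  Both training arms are run for three seeds; the
ablation compares across-seed means (between-seed spread is comparable
to the effect size at this scale), and the end-to-end numbers use the
best run by validation AP at IOU 0.5, the usual rerun-selection
protocol.  The reproduction script instead reports the default-regime
pipeline (7–11 cells, 40% contact, textured high-contrast interiors).
The LOI annotation benchmark uses 50 nucleus images of 256 × 256 px
with 30 nuclei each.  These sizes were chosen so the full pipeline
retrains in minutes; accuracy saturates well before these budgets on
the synthetic scenes.

## Numerical and degenerate-input choices

* Coordinates are 0-based (row, col); centroids fractional, DoG peaks
  integer.
* Probability/log clamping at 1e-6; loss terms are provably
  non-negative and finite for inputs in [0, 1].
* Proposal NMS breaks score ties toward the lowest (row, col) cell.
* An empty instance list yields an all-background mask rather than an
  error; an empty prediction set evaluates to the defined empty-case
  metric conventions above.
* Scenes that cannot satisfy the spacing constraint after bounded
  retries raise an error naming the constraint.

## Known limitations

* The trainable core is a compact numpy implementation; it is
  single-threaded and desk-scale by design.  The architecture is
  config-scalable, but training large real datasets would require
  porting the `loiseg.nn` layer contracts to a GPU framework.
* The exact loss formulation (probabilistic-union cross-entropy,
  pairwise-product overlap, stop-gradient boundary co-training) is one
  concrete instantiation of the stated consistency principles; the
  alternatives (per-pixel max union, sum-minus-max overlap) are noted
  in the code and would be straightforward to add behind config
  switches.
* Auxnet co-training helps when cell-cell borders are genuinely
  ambiguous; on high-contrast scenes whose borders are already easy it
  is neutral.
* No tiled inference: images are processed whole.
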