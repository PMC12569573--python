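# Methods

## Problem and quantities

Left-ventricular non-compaction (LVNC) is characterised by excessive
trabeculation of the LV inner wall.  The toolkit quantifies it on
short-axis MRI stacks via the trabecular volume percentage

```
TV% = 100 · V_T / (V_T + V_EL)
```

where both volumes are approximated as sums of per-slice segmented areas
over a patient's stack.  The compact external layer (EL, label 1) is the
denominator's wall component; the inner cavity (IC, label 2) is excluded
from the wall volume.  A patient is flagged LVNC when TV% strictly exceeds
27.4 %, a threshold validated in the clinical literature for this ratio.
Tie handling at exactly 27.4 is not clinically specified; the strict
inequality was chosen to mirror the convention of ratio criteria such as
NC/C > 2.3.

## Synthetic phantoms

No clinical images ship with the package, so all stages are exercised on
procedural phantoms.  A slice is built in polar coordinates around the
image centre: a cavity disk (IC), a compact annulus of given wall thickness
(EL), and trabeculae painted as random disks attached to the cavity side of
the wall.  Trabecular painting is exact: the target pixel count
`round(f/(1−f) · area_EL)` is topped up or peeled back pixel-by-pixel
(outermost cavity pixels first, innermost trabecular pixels first), so the
realised area fraction matches the requested `trabecular_fraction` to one
pixel.  This exactness is what makes the end-to-end TV% recovery tests
sharp rather than statistical.

Intensities are fixed class means (background 0.20, EL 0.55, IC 0.85,
T 0.40) plus additive Gaussian noise (default sigma 0.05), clipped to
[0, 1].  The values are arbitrary but chosen so the hardest contrast is
EL vs T, qualitatively matching real slices while remaining learnable by a
small network in minutes.  Degenerate categories reproduce the two
discard classes of quality control: *no ring* (an arc of the annulus
removed; angular extent 45–120° when drawn randomly) and *poor quality*
(cavity radius at most a tenth of the image plus at least one bright
streak/blob artefact, painted into the intensity image only).

Patient stacks default to 7 slices, with ring geometry scaled by
`0.65 + 0.35·sin(π(i+½)/n)` along the stack so extreme slices are smaller,
as in real acquisitions.  Cohorts follow the four-group composition of an
LVNC study population — proportions 293:78:69:10 (P/H/X/T) over 450
patients, apportioned by largest remainder — with per-group trabecular
fraction ranges (P 0.15–0.30, H 0.30–0.45, X 0.10–0.40, T 0.15–0.35) chosen
so that group H is predominantly above the 27.4 % threshold and P
predominantly below, and 6–9 slices per patient.  Cavity radius is drawn
at 0.20–0.27 of the image side and wall thickness at 0.28–0.40 of the
cavity radius; the latter coupling guarantees that the trabecular band
always fits inside the cavity at the highest group fractions.

What the phantoms do **not** model: MRI physics (bias fields, k-space
artefacts, partial-volume effects), anatomical shape variability
(non-circular ventricles, papillary muscles), 3-D slice geometry
(thickness/gap), or intensity distributions of any scanner.  Passing tests
therefore demonstrates correctness of the algorithms and the learnability
of the segmentation task under this image model — not clinical performance.

The simulated QC triplets stand in for two trained detector models.  They
are constructed to satisfy the documented contracts: open-ring confidence
is ≥ 0.5 exactly when the ring has an opening (rising with the angle);
cavity confidence is `0.97·ρ² − 0.35·(1−s) − 0.08·artifacts + ε` clipped to
[0, 1], with ρ the ring-completeness fraction, `s` a saturating function of
the cavity bounding-box area fraction (zero below 0.03, one above 0.08) and
ε uniform ±0.02; the reported area is the cavity bounding-box fraction with
uniform ±0.005 noise.  Under these defaults normal phantoms fall in the
cascade's keep region and no-ring/poor-quality phantoms in its discard
regions with wide margins, which the generator/cleaner contract test
verifies empirically.

## Quality-control cascade

Slice triplets `(conf_valid, conf_open, area)` pass a two-stage rule:

1. **Stage 1** discards iff `conf_open − 5.526·conf_valid > −4.3` (strict;
   boundary points are retained for stage 2).  At `conf_open = 0` this
   implies a minimum cavity confidence of 4.3/5.526 ≈ 0.778.
2. **Stage 2** keeps at `conf_valid ≥ 0.88`, rejects below 0.83, and inside
   `[0.83, 0.88)` keeps iff the area clears the line through the anchors
   (0.88, 0) and (0.83, `area_ref` = 0.02) — a negative slope, so higher
   confidence tolerates a smaller cavity.  The published form of this
   second line gives no printed coefficients, so it is parameterised by the
   two anchors; `area_ref` is expressed as an image-area fraction to stay
   resolution independent.  The line is evaluated in two-point form, which
   keeps the engine bit-identical to a literal transcription of the rule at
   exact floating-point ties.

Both boundary values at the band edges are inclusive on the keep side
(`conf_valid = 0.88` keeps; `= 0.83` enters the band), consistent with a
closed band and the zero-area anchor.  Decisions are monotone: raising
`conf_open` never rescues a slice, raising `conf_valid` or `area` never
discards one; a property-based suite asserts this on random pairs.  After
cleaning, patient TV% is recomputed over surviving slices only; a patient
with no surviving slice is flagged excluded (`None`) rather than given a
number.

## ROI preprocessing

A detector proposes a box with confidence `prob`; the square crop side is
`max(w, h)·(1 + (1 − prob))`, rounded to the nearest pixel — monotone
non-increasing in confidence, equal to the box side at full confidence and
twice that at zero.  Crops outside the image are zero-padded (the source
convention is unstated; padding preserves geometry for boxes near borders).
Images are resampled bilinearly and z-scored (constant inputs map to
zeros); masks follow the identical geometry with nearest-neighbour
resampling so labels stay categorical.  The output side defaults to 800 px;
tests run 64–128 px.

## Segmentation network

The network is a U-Net with a transformer bottleneck.  Each encoder level
is two (conv 3×3 → batch norm → ReLU) units followed by 2×2 max pooling,
doubling channels; the bottleneck map is split into patches, linearly
embedded with learned positional encodings, passed through pre-norm
transformer layers (multi-head self-attention + 4× MLP, both residual),
projected back and reshaped; each decoder level nearest-neighbour upsamples,
concatenates the same-level encoder skip and applies another double conv
block; a 1×1 convolution and per-pixel softmax produce four class
probabilities.  ViT hyperparameters are all configurable (defaults: patch 1
on the bottleneck grid, depth 4, width 256, 4 heads; the scaled-down test
instance uses depth 2, width 64, patch 2).  The fusion operator between
transformer output and skips is concatenation, following the TransUNet
lineage.

The whole engine is numpy with hand-written backpropagation (im2col
convolutions, explicit batch-norm/layer-norm/attention gradients).  Its
correctness is established by finite-difference gradient checks through the
full network and by loss-level oracle tests, not assumed.

**Loss.**  `L = L_Lovász + L_BCE`.  The Lovász-Softmax term applies the
Lovász extension of the per-class Jaccard loss to the softmax
probabilities, averaged over the classes present in the batch labels (the
batch is treated as one pixel population).  The weighted BCE term is
one-vs-rest cross-entropy per channel, with every pixel's four channel
terms scaled by the weight of that pixel's true class; `"auto"` weights are
inverse relative pixel frequencies on the training set, normalised to mean
1.  This combination counteracts the small pixel share of the trabecular
class.  Gradients flow through both terms to the logits via the softmax
Jacobian.

**Optimisation.**  RAdam with initial learning rate 0.005 (beta/epsilon at
reference defaults, variance rectification threshold ρ > 4).  Augmentation
applies one of {90°, 180°, 270°} rotations with probability 0.25, jointly
to image and mask, training samples only.  Epoch count and early stopping
are configurable (patience 10 on validation loss); runs are a pure function
of the seed.

**Splitting.**  Cross-validation is at patient granularity: 20 % of
patients held out for testing, 5 stratified folds over the remaining 80 %,
stratified by the boolean TV% > 27.4 label (scikit-learn's stratified
splitters underneath).  Each validation fold's LVNC count is within one
patient of proportional.

## Evaluation

Dice per foreground class is macro-averaged over slices, and the summary
value is the arithmetic mean of the three class Dices (background never
enters).  Both-empty classes score 1 by convention.  Published per-group
averages for this kind of pipeline are not always consistent with the mean
of their own class values, so no external averaging convention is assumed
beyond the one stated here.

## Problem sizes and numerical choices

The test suite trains the scaled-down instance — 64 px inputs, 2 encoder
levels, base 8 channels, ViT depth 2/width 64 — on 200 phantom slices for
6 epochs (batch 8), three seeds, reaching mean held-out foreground Dice
well above the 0.85 bar in a few minutes on a single CPU; these sizes are
the package's own desk-scale defaults for its tests.  Probabilities are
clipped at 1e-7 inside the BCE; batch/layer norm use eps 1e-5; the
Lovász sort is stable, and ties in argmax predictions resolve to the lowest
class index.  Bounding boxes use the half-open pixel convention (a pixel at
(r, c) occupies [r, r+1) × [c, c+1)), so box extents equal pixel counts and
normalised labels of a full-frame box are exactly (0.5, 0.5, 1, 1);
connected components are 8-connected, and equal-area component ties break
on the topmost-then-leftmost pixel.

## Known limitations

* The phantom image model is deliberately simple; Dice numbers on phantoms
  do not transfer to clinical data.
* The QC triplet simulator encodes the contracts it is tested against; it
  demonstrates the cascade's behaviour, not detector accuracy.
* Training at the full 800 px scale is supported by the architecture but
  not by the pure-numpy engine's speed; the toolkit targets desk-scale
  experimentation.
* Only 2-D summed-area volumes are computed; slice thickness and gaps are
  not modelled.
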