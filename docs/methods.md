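# Methods

## Problem and pipeline

An anteroposterior hip radiograph images both proximal femora — the most
common site of benign bone tumors, a frequent site of metastases and primary
sarcomas, and the most common site of tumor-secondary pathological fracture.
`femursplit` classifies each proximal femur as *no tumor*, *benign* or
*malignant* from such bilateral films. Because bilateral tumors are rare,
the pipeline converts each film into two single-femur images that share one
orientation, which (a) doubles the sample count, (b) turns most films into
one lesioned and one normal femur, enriching the normal class, and (c) lets
a classifier concentrate on one femur at a time.

Stages, in fixed order:

1. **Min-max normalization**: x ↦ (x − min)/(max − min) per image, absorbing
   exposure and brightness differences between films. A constant image maps
   to all zeros with a warning.
2. **Binarization**: foreground = every strictly positive pixel. Applied to
   the raw image; after min-max normalization the minimum pixel is exactly 0,
   so the rule is equivalent on either, and the raw image is robust to the
   constant-image degenerate case.
3. **Artifact removal**: binary opening (erosion then dilation) with a square
   kernel (default 15 px at the native 850×500 scale; erosion and dilation
   use the same element, one iteration each), followed by keeping the largest
   connected component (default on). Opening removes structures thinner than
   the kernel — laterality markers, letters, noise; the largest-component
   guard removes compact artifacts thicker than the kernel, which opening
   alone cannot.
4. **Midline**: `floor((leftmost + rightmost)/2)` of the foreground column
   span. The mean (not median) of the two end coordinates is used; floor
   breaks ties. The midline column itself belongs to the right half.
5. **Split and flip**: left half = columns `[0, midline)` kept as-is; right
   half = columns `[midline, width)` mirrored. "Left"/"right" are *image*
   coordinates (AP films mirror the patient); the `flipped` flag recorded on
   every output makes the convention invertible.

Training images are then augmented six-fold (original + five crops 10%
smaller *per linear dimension* — window `round(0.9·H) × round(0.9·W)` —
anchored flush at the four corners and centered, rescaled back by bilinear
interpolation), equalized (global histogram equalization, 256 bins) and
resized to 500×300. Evaluation images get equalize+resize only; there is no
test-time augmentation. The order crop → equalize → resize is fixed.
The *basic* ablation scheme skips stages 2–5 and classifies the whole
radiograph resized to 500×500; its single label is the most severe per-side
label (malignant > benign > no_tumor), a collapse rule this package defines.

## Training protocol and backbone

The reference protocol is SGD on cross-entropy, 50 epochs, batch size 8,
learning rate 0.1 divided by 10 every 10 epochs
(`lr(e) = lr₀ / 10^⌊e/10⌋`, assertable from the training log); momentum and
weight decay default to 0 (unstated in the protocol; configurable).
Backbones are pluggable by name. ResNet50 / Inception v3 / EfficientNet-b1/2/3
are registered as torch-backed options (grayscale planes are duplicated to
three channels where required; EfficientNets accept one channel).

The in-package `tiny` backbone is a small numpy CNN used by the test suite
and desk-scale runs: two 3×3 convolution (edge-replicate padding) + ReLU +
2×2 max-pool blocks, a flatten, and a linear head; default widths (8, 16);
forward and backward passes are explicit (gradients are verified against
finite differences in the tests). Three deliberate choices:

* **Flatten head, not global average pooling.** GAP dilutes a small-lesion
  signal ~50-fold before the classifier; at desk-scale sample sizes GAP-head
  variants plateau near 0.7 accuracy on separable phantoms while the flatten
  head reaches ~1.0.
* **Edge-replicate convolution padding.** Zero padding makes the border ring
  contrast with any non-zero background and produces spurious border
  responses that pollute class-activation maps.
* **Near-zero head initialization** so an untrained network predicts
  approximately uniform scores.

Inputs to this backbone are standardized per image (zero mean, unit
variance) — its input convention, analogous to the fixed mean/std
normalization of torch image models. Desk-scale runs use epochs ≈ 6–12,
initial LR 0.01, momentum 0.9 (the 0.1 reference rate is tuned to
full-scale backbones and destabilizes the tiny network); the protocol
defaults are unchanged and these overrides are always explicit in configs.

## Evaluation

All multi-class metrics are one-vs-rest on the 3×3 confusion matrix, macro
averaged (unweighted mean over classes): accuracy = trace/total; precision,
sensitivity, specificity = TN/(TN+FP), and F1 per class. A zero-denominator
ratio contributes 0 with a warning (conservative and visible); a class
absent from both truth and prediction is skipped and the mean runs over the
remaining classes. Cross-validation is fivefold by default, stratified by
label and **grouped by source radiograph**, so no augmented copy and no
contralateral femur can leak between a fold's train and eval sets; per-fold
metrics are summarized as mean ± sample SD (n−1 denominator).

ROC-AUC is computed both ways — micro (all one-vs-rest indicator/score pairs
pooled into one ROC; the headline value) and macro (mean of per-class AUCs)
— because "micro-average" is often used loosely for either; both are
labelled. The 95% CI is a percentile bootstrap over samples (default 2000
resamples, seeded). Two raters' accuracies are compared with a Pearson
chi-squared test on the 2×2 correct/incorrect table, 1 df, no continuity
correction; a warning is attached when an expected cell is below 1.

## Grad-CAM

For a chosen convolutional layer (default: post-ReLU output of the last
convolution block) with feature maps A_k: channel weights are the spatial
means of ∂(pre-softmax class score)/∂A_k, obtained from the network's own
backward pass; the heatmap is ReLU(Σ_k w_k A_k), bilinearly upsampled to the
input shape and max-normalized to [0, 1] when its maximum is positive. A
softmax-score backward signal was evaluated and localized slightly worse;
the pre-softmax form is kept. Overlay rendering (viridis over the grayscale
input) is cosmetic and untested.

Localization quality at desk scale is training-seed dependent: across eight
training seeds of the standard strong-lesion fixture the argmax-in-box rate
(box dilated by 4 px, about one pooled-grid cell) ranged roughly 0.4–0.9.
Crop-augmented training, weight decay 1e-3 and narrow widths (4, 8) each
measurably improve it; the seeded test uses this configuration. The
acceptance script reports the rate at whatever seed it is given.

## Phantom generator

Each phantom is an ellipse of "body" on an exactly-zero background — the
contract stage-2 binarization relies on — with: a horizontal body offset
(|offset| < 0.25 keeps both femora in frame; cohorts sample ±0.12),
a per-image exposure band (min/max intensity sampled per image), an optional
thin bright "R"-like corner marker drawn at body-maximum intensity (it
survives binarization and is removed only by morphology, exercising the
opening stage), and two femur structures (head circle + shaft) symmetric
about the body axis. Lesions are elliptical intensity perturbations with a
logistic edge of configurable softness: sharp edges model the narrow zone of
transition typical of benign lesions, wide hazy edges the aggressive
pattern. Defaults: benign = bright (blastic), small, sharp; malignant =
dark (lytic), larger, wide transition, with a faint sclerotic rim — real
lytic lesions border reactive bone, and a purely featureless dark void would
also be invisible to a rectified activation map. Lesion centers are jittered
over the head/neck/trochanter-to-proximal-shaft band. Native size 850×500
(1.7:1); the suite uses 170×100 with a 5 px kernel for speed.

Cohorts follow a radiograph-level composition; all bilateral-tumor
radiographs are malignant-bilateral (the only assignment consistent with
femur-level counts 94/120/324 arising from 89/120/60), and every other
tumor radiograph gets its lesion on a uniformly random side (the side
distribution is otherwise unspecified). The default composition yields 269
radiographs → 538 femur images.

What the phantom does **not** emulate: bone texture and trabecular
structure, cortical boundaries, soft-tissue layers, pelvis/acetabulum
anatomy, fractures or implants, projection geometry, scatter or detector
noise. Tests passing on phantoms therefore validate the *mechanics* of the
pipeline (counts, geometry, label bookkeeping, optimization, metric
arithmetic, heatmap wiring) — not clinical performance, which requires real
data and full-scale backbones.

## Numerical and I/O choices

* Normalized images are written as 16-bit grayscale PNG (values × 65535) to
  avoid quantization before training; 8-bit is optional. DICOM input applies
  RescaleSlope/Intercept and MONOCHROME1 inversion before normalization.
* Resizes are bilinear with outputs clipped to [0, 1]; crops are
  deterministic (no jitter).
* Max-pool gradient splits evenly across ties; convolution is 'same' with
  edge-replicate padding; He initialization throughout except the near-zero
  classifier head.
* Fold assignment uses stratified group K-fold with a seeded shuffle; one
  pipeline seed governs cohort generation, folds, per-fold training seeds
  and the AUC bootstrap, so a run is reproducible from its saved
  `config.yaml`.
* Per-image inference wall-clock time is recorded on every prediction and
  reported, never asserted.

## Limitations

The tiny backbone exists to make the pipeline testable end-to-end on one
CPU; its accuracy and heatmaps say nothing about full-scale backbones.
Printed clinical performance figures require the original (non-shared)
patient data and GPU training and are out of scope. The chi-squared
comparison treats per-image decisions as independent; paired or
multi-reader designs need other machinery. Grad-CAM localization is
seed-sensitive at this scale (see above).
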