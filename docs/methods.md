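# Methods

## Problem and model

`chipcnn` grades the gemcitabine-resistance level (four classes: parental,
early, intermediate, late) of bladder-cancer cells cultured in a 3D
microfluidic chip, from single-channel fluorescence (F-actin) images. The
biological signal is graded infiltration: the more resistant the cell line,
the farther and more numerously its cells invade the central collagen gel
from their seeded side channel. The classifier is a small convolutional
network over 64x64x3 inputs:

    conv 3x3/16 -> ReLU -> maxpool 2x2
    conv 3x3/32 -> ReLU -> maxpool 2x2
    conv 3x3/64 -> ReLU -> maxpool 2x2
    dense 128 -> ReLU -> dense 4 -> softmax

with "same" padding and stride 1, giving the spatial cascade 64->32->16->8
and 548,516 trainable parameters. Training minimises softmax cross-entropy
(batch mean of -log p_true) with Adam (beta1 0.9, beta2 0.999, epsilon 1e-7,
batch size 32) under one of three learning-rate schedules evaluated per
epoch t:

    constant      alpha_t = alpha0
    exponential   alpha_t = alpha0 exp(-k t),            k = 0.1
    step          alpha_t = alpha0 eta^-floor(t/gamma),  eta = 2, gamma = 5

with alpha0 in {1e-4, 1e-3}. The forward/backward passes and the optimizer
are implemented directly in NumPy (im2col convolutions, fused
ReLU/max-pool); gradients are verified against central finite differences in
the test suite.

Padding, pool geometry and weight initialization (variance-scaling uniform,
seeded) are recorded in `NetworkConfig` as explicit assumptions; the
kernel-depth of the deeper conv layers follows the incoming channel count
(16 and 32), the only dimensionally consistent reading. The loss clips
probabilities at 1e-12. Bias-corrected Adam moments are used throughout.

## Study design

Each chip carries 16 regions of interest (ROIs) between pillar pairs; each
ROI is a 27-slice z-stack. Seven slices (z = 1, 3, 5, 14, 23, 25, 27,
1-based) are kept per stack — adjacent slices are near-duplicates and would
contribute redundant features. Slices are resized bilinearly to 64x64,
scaled to [0, 1] by the source format's maximum, and the grayscale channel
is replicated to three channels.

Six chips per level are generated; one full chip per level is held out as
the test set (chip-disjoint, so chip-specific features cannot leak), and the
remaining images are shuffled per level into 90% training / 10% validation
(floor rounding). Two ROI stacks are removed from trailing (never-test)
level-0 chips, reproducing the bookkeeping 658 + 3x672 = 2,674 images with
training/validation/test = 2,004/222/448. Validation is deliberately not
chip-disjoint: only an image-level 90/10 split reproduces those per-level
counts.

Cross-validation follows a hybrid design: the train+validation pool is
shuffled once and cut into k = 10 near-equal folds; fold i trains on the
other nine (its own partition is the validation monitor) and every fold is
evaluated on the same fixed test chips. Fold assignment is governed by one
seed; per-fold training seeds are derived children, so the whole protocol is
reproducible bit-for-bit.

Training-set augmentation (never applied to validation or test) mirrors the
classic label-preserving trio: vertical flip with probability 1/2, zoom-in
by a uniform extra magnification of 10-20% with a centered crop back to
64x64, and vertical translation by U(-5%, +5%) of the height rounded to
whole rows, vacated rows zero-filled. Zoom is interpreted as magnification
(zoom-in); sub-pixel shifts are rounded to avoid interpolation ambiguity at
64x64. The ablation grid crosses {no augmentation x constant rate} and
{augmentation x (constant, exponential, step)} over both alpha0 values —
eight configurations sharing one fold assignment.

## Synthetic chip images

The original microscopy dataset is not publicly deposited, so the package
ships a seeded generator that emulates the study's structure end-to-end.
Each ROI is rendered as isotropic Gaussian cell blobs on a dark background:
a dense resident band (Poisson(22) cells in the top 14 rows of a 96x96
frame, the seeded-channel side) plus Poisson(rate_level) infiltrating cells
whose penetration depths beyond the band are gamma-distributed (shape 4)
with mean depth_level. Defaults per level 0..3:

    rate   1, 10, 25, 48   cells per ROI
    depth  3, 11, 22, 35   pixels

Blob radii are N(2.6, 0.5) px (clipped at 0.8), amplitudes U(0.6, 1).

Two nuisance properties of real chip imaging are emulated because they are
what the augmentation transforms exist to absorb. First, registration: the
channel edge never lands on exactly the same row after stitching and
ROI cropping, so each ROI draws a vertical band offset U(0, 6) px. Second,
orientation: a chip can be mounted either way up under the microscope, so
chips alternate vertical orientation (even-indexed chips band-on-top,
odd-indexed flipped). Without these, augmentation would have nothing to be
invariant to and could only dilute the training signal; with them, a
classifier trained without augmentation overfits the orientations and
registrations of its training chips and degrades sharply on held-out chips
— the qualitative behaviour expected of real chip data, for which training
without augmentation roughly halves sensitivity and the useful
label-preserving transforms are precisely vertical flip, vertical shift
and zoom.
Slices away from the mid-plane are blurred with a Gaussian of sigma = 0.12 x
|z - mid|, emulating defocus while keeping adjacent slices nearly identical;
additive N(0, 0.02) noise is applied per slice and intensities clipped to
[0, 1]. Geometry streams are keyed by (seed, chip, roi) — all slices of one
stack image the same physical cells — and noise streams by (seed, chip, roi,
z), so any single slice is reproducible in isolation.

The per-level rates and depths are the package's own choice (no numeric
counts exist to copy): they were set so that the three morphology statistics
(maximum infiltration distance, infiltrated area, connected-component cell
count) increase strictly and significantly with level, and so that a
well-trained classifier separates the four grades from single images at the
roughly 90-95% accuracy characteristic of this assay, with residual
confusion confined to adjacent grades. A `degenerate()` control makes rate and depth
level-independent, which must (and does) drive downstream test accuracy to
chance.

What the generator does not emulate: cytoskeletal texture, clustered or
elongated cell morphology, the bright-field/pillar channel, the endothelial
co-culture channel, illumination gradients, and chip-level random effects
(chips differ only by sampling). Passing tests therefore demonstrate that
the pipeline recovers graded morphological structure when it exists and
degrades to chance when it does not — not that the network would reach any
particular accuracy on real microscopy data.

## Evaluation

Per fold, a 4x4 confusion matrix (rows actual, columns predicted; argmax
ties toward the lowest class) is reduced one-vs-rest per level to TP/FN/FP/
TN, from which accuracy, precision, recall, F1, sensitivity (== recall) and
specificity are computed in percent. Macro averages are unweighted over the
four levels; fold summaries report mean and sample (n-1) standard deviation
over folds, and fold-averaged confusion matrices are real-valued. "Overall
accuracy" (trace/total) is reported alongside, since the one-vs-rest
accuracy also credits true negatives and sits far above chance even for a
collapsed classifier. ROC curves sweep every distinct score threshold in
descending order with ties grouped; AUC is the trapezoidal area. Undefined
metrics (zero denominators) are reported as NaN, never silently 0.

## Numerical and scale choices

* float32 parameters and activations for training; float64 for softmax/loss
  and for the finite-difference gradient checks.
* The acceptance checks that train networks run at a reduced scale chosen
  once: 2 chips per level (one train+validation, one test chip per level),
  3 folds, 20 epochs for the separable-recovery grid and 10 for the
  degenerate control. The full-scale configuration
  (`configs/full_scale.yaml`) runs the same code paths.
* Dataset regeneration is byte-identical for a given (parameters, seed);
  training is deterministic given its seed.

## Known limitations

* Single-slice 2D classification only; no 3D convolutions over the z-axis.
* No early stopping or hyperparameter search; epoch count is a config knob
  (default 50) since no canonical value exists.
* The NumPy network targets clarity and small-scale reproducibility, not
  GPU-scale throughput.
* Transfer-learning baselines and GAN-based augmentation/deblurring are out
  of scope.
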