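# Methods

## Problem and pipeline

`paplite` implements a computer-aided diagnosis (CADx) pipeline for
multiclass Pap-smear cytology classification built from five stages:

1. **Image preparation** — images resized to a common frame (224×224×3 for
   full-scale runs), stratified 70/30 train/test split for CNN training,
   and on-the-fly geometric augmentation of training mini-batches only
   (scale 0.6–2.6, shear ±59°, translation ±46 px, rotation ±90°, axis
   reflection; reflect padding for out-of-frame pixels).
2. **Attention-augmented lightweight CNNs** — a multi-head self-attention
   block inserted between the last convolutional stage and the final
   pooling layer of a compact CNN, trained end to end with categorical
   cross-entropy.
3. **Dual deep-layer feature extraction** — per image, one feature vector
   from the final pooling layer and one from the self-attention layer.
4. **Haar-DWT fusion and cross-network ensembling** — the two vectors are
   concatenated and compressed by a row-wise 1-D Haar wavelet transform
   (approximation coefficients only, level 1 or 2), then concatenated
   across networks.
5. **ANOVA selection and classical classification** — per-column one-way
   ANOVA F-ratios rank the pooled features; the top-k subsets feed a
   battery of seven classifiers under repeated stratified 5-fold
   cross-validation, with Grad-CAM heatmaps for visual explanation.

## The attention block

Given a feature map `F ∈ R^{H×W×C}`, the sequence `X ∈ R^{N×C}` (`N = HW`)
is projected to queries/keys/values `Q = X W_Q`, `K = X W_K`, `V = X W_V`
with `W_Q, W_K, W_V ∈ R^{C×d}`. The embedding is split across `h = 8`
heads, `d = h·d_k`, each head computing
`softmax(Q_i K_iᵀ / √d_k) V_i` on its contiguous `d_k`-column slice; the
concatenated heads are projected back by `W_O ∈ R^{d×C}`. We fix `d = C`
(so `d_k = C/8`: 160 for the 1280-channel backbones, 64 for the
512-channel one), which keeps the attention output `N×C` and makes the
downstream dimension contracts hold exactly. No positional encoding is
used, so the block is permutation-equivariant over spatial positions.
Head slices are contiguous column blocks (the standard convention).
Attention features are taken **after** the `W_O` projection, i.e. the full
attention-enhanced representation `SA(X)`.

The wiring is `conv → flatten → attention → unflatten → global average
pool → FC → softmax`. A consequence worth stating plainly: under this
wiring with mean aggregation, the pooled attention-layer feature vector
and the final-pooling-layer feature vector are numerically identical (both
are the positional mean of `SA(X)`). The dual-layer stage therefore acts
as a structured duplication ahead of the wavelet step in this
implementation; the two endpoints are still exposed separately because
they are distinct taps of the model and alternative aggregations can be
swapped in.

## Neural network implementation

The CNNs, their SGDM training loop and Grad-CAM are implemented directly
on NumPy with hand-written forward/backward passes (im2col convolution,
batched attention with an explicit softmax backward). Correctness of the
backward pass is enforced by central-finite-difference tests. Training
uses SGD with momentum 0.9, L2 weight decay 1e-4, fixed learning rate (no
schedule), mini-batch 5, 50 epochs by default.

Named backbones: `toy_cnn` is a 3-block CNN (8/16/16 channels, stride 2)
used by the test suite; `resnet18`, `mobilenet` and `efficientnetb0` are
compact randomly initialised strided conv stacks whose final channel
widths (512 / 1280 / 1280) match the published architectures so that every
feature-length contract holds. They are stand-ins built in this package
— not the pretrained ImageNet networks — and are suitable for shape
contracts, plumbing and desk-scale experiments, not for reproducing
full-scale accuracies.

Numerical choices: softmax/log epsilon 1e-12; inputs scaled to [0,1] and
zero-centred (−0.5) before the first convolution — without centring the
all-positive pixel range stalls small-scale SGDM runs.

## Haar fusion

The orthonormal two-tap filter is fixed:
`CA_i = (v_{2i}+v_{2i+1})/√2`, `CD_i = (v_{2i}−v_{2i+1})/√2`, which gives
the Parseval identity `‖CA‖² + ‖CD‖² = ‖v‖²` used by the tests (and hence
the energy bound `‖CA‖ ≤ ‖v‖`). Detail coefficients are computed and
discarded. Standard (not dual-tree) DWT; levels 1 and 2 only. Lengths:
1024 → 512 → 256 and 2560 → 1280 → 640. All in-scope lengths are
divisible by 4; odd inputs are handled by reflecting the trailing sample,
so the transform is total. The implementation agrees with PyWavelets'
`haar` analysis to machine precision (checked in tests; PyWavelets is an
oracle, not a dependency of the package).

## ANOVA selection

Per column, `F = MS_between / MS_within` with df `(K−1, n−K)`; p-values
from the F distribution are reported for inspection only — selection is
rank-based top-k, so no multiple-testing correction applies. Degenerate
columns: zero within-class variance with unequal means ranks first
(`F = +∞`); a globally constant column is defined as `F = 0` and ranks
last. Ties break toward the lower column index for determinism. The
selection sweep (default grid 100…1500 step 100, clipped to the pool
size) computes the ranking **once on the full matrix** and cross-validates
each top-k subset. This reproduces the procedure as published; note it
lets the ranking see all samples, so sweep accuracies are mildly
optimistic relative to fold-internal selection. The ANOVA-vs-planted-
feature recovery checks are unaffected (they compare against generator
ground truth).

## Classifier battery and evaluation

Seven classifiers: linear / quadratic / cubic / Gaussian-kernel SVMs
(one-vs-one voting, box constraint 1), Euclidean and cosine 10-NN, and
LDA. The SVM kernel scale is `√p` (`gamma = 1/p` after standardisation) —
a documented approximation to a toolbox's proprietary automated kernel
scaling. Standardisation statistics are fit on training folds only (a
canary-feature test enforces this); the cosine KNN skips standardisation
because the metric is scale-free.

Metrics come from one-vs-rest binarised confusion matrices:
Sens = TP/(TP+FN), Spec = TN/(TN+FP), Prec = TP/(TP+FP),
F1 = 2TP/(2TP+FP+FN), MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
Acc = trace/total. Macro values are unweighted class means; the
multiclass MCC is the mean of per-class binary MCCs (the binary formula is
the defined quantity; its multiclass generalisation is a choice). Zero
denominators define the metric as 0 and are flagged. ROC analysis is
one-vs-rest with trapezoidal AUC; scores are posterior estimates where
the classifier provides them (KNN, LDA) and decision values otherwise
(SVMs) — raw multiclass LDA discriminant values rank poorly one-vs-rest
even at near-perfect accuracy, so posteriors are the correct score source.

Evaluation is stratified 5-fold CV repeated 5 times (seeds derived from
the run seed); per repeat, metrics are computed on the confusion matrix
summed over test folds. The across-classifier significance test is a
one-way ANOVA on the first repeat's per-fold accuracies — 7 classifiers ×
5 folds gives the Columns/Error/Total df structure 6/28/34. Unbalanced
group sizes are handled by the general one-way decomposition.

## Grad-CAM

Channel weights are spatial means of the gradient of the target class
logit with respect to the tapped activations (default: the last
convolutional stage, where spatial resolution is best; the attention
sequence is also supported). The map is `ReLU(Σ_k w_k A^k)`, bilinearly
upsampled and divided by its maximum — max normalisation (not min–max) so
an identically zero map stays zero and is flagged rather than silently
rescaled. The jet colormap is an explicit piecewise-linear formula
(`r = clip(1.5−|4v−3|)`, `g = clip(1.5−|4v−2|)`, `b = clip(1.5−|4v−1|)`),
so overlays are bit-reproducible.

## Synthetic fixtures: what they are and are not

The image generator renders two concentric filled ellipses — nucleus
inside cytoplasm — with per-class nucleus radius (mean/sd), nucleus-to-
cytoplasm area ratio, chromatin texture noise and stain hue, plus mild
global acquisition noise. Morphology parameters are stated in pixels on a
224 px frame and scaled with the frame. The nucleus ellipse uses axes
`(r·s, r/s)` so its area is exactly `πr²` for any sampled aspect, which
makes the Monte-Carlo area check exact in expectation. A single top-level
seed spawns per-image substreams, so any image regenerates bit-identically.

The feature generator plants `k` informative columns whose class means sit
`effect_size · noise_sd` apart (class-to-mean assignment permuted per
column) in otherwise exchangeable Gaussian noise, and returns the ground-
truth informative index set.

What passing tests show: the plumbing, the dimension contracts, the
statistics and the selection/evaluation machinery behave correctly, and
the pipeline recovers planted class structure. What they do not show:
performance on real cytology. The fixtures have none of the hard parts of
real Pap smears — staining variability, overlapping cells, debris,
out-of-focus regions, inter-lab acquisition differences — and the class
signal (hue, nucleus size) is far cleaner than real morphology. Full-
scale results additionally require the pretrained backbones, which this
package does not ship.

## Desk-scale problem sizes

The end-to-end tests and the acceptance script run the pipeline at sizes a
laptop CPU handles in seconds: 5 classes × 50 images at 32×32 on
`toy_cnn`, 5 epochs, learning rate 0.01, no augmentation, 2 CV repeats.
These choices are the package's own desk-scale defaults: the Table of
full-scale hyperparameters (batch 5, lr 1e-3, 50 epochs) describes 224 px
pretrained-backbone training, where a 1e-3 step is appropriate; the tiny
toy network at 32 px needs a larger step to move in 5 epochs, and the
±46 px translation range exceeds a 32 px frame, so augmentation is off at
this scale. The high-separability morphology preset
(`high_separability_morphologies`) spreads hue and nucleus size widely —
it is the "easily separable class structure" the end-to-end checks are
defined on.

## Known limitations

- Named backbones are random-init stand-ins; no transfer learning.
- The dual-layer endpoints coincide under the adopted wiring (above).
- The selection sweep ranks on the full matrix (as published), which is
  not leakage-free; fold-internal selection would be the stricter design.
- The SVM kernel-scale rule approximates a proprietary auto-scaling.
- Validation-frequency for training history is a free config value (the
  source material assigns it inconsistently across datasets).
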