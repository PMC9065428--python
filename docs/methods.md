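# Methods

`oarseg` implements a 3D convolutional auto-segmentation pipeline for five
head-and-neck organs-at-risk (brainstem, mandible, left/right parotid
glands, cervical spinal cord) in CT, designed for the small-dataset
regime: multi-window intensity normalisation, a residual 3D U-Net with
deep supervision, three candidate training objectives, heavy spatial
augmentation, a plateau-driven training schedule, and symmetric
surface-distance evaluation.  Everything is exercisable end-to-end on
synthetic CT phantoms, with no external dataset.

## Input normalisation: clinical windows as channels

CT intensities are calibrated Hounsfield units, so fixed intensity windows
carry transferable meaning.  A window `(L, W)` defines the ramp

    f(I) = clip((I - (L - W/2)) / W, 0, 1)

The baseline input is a single channel through the full-width window
`L=488, W=3024`, which maps `[-1024, 2000]` HU onto `[0, 1]`.  The
multi-window input stacks three standard radiological viewing windows as
channels: soft tissue `(40, 400)`, bone `(400, 1800)` and brain `(40, 80)`.
The three contrast values are standard-of-practice defaults and are
exposed in the `windows:` config section; narrow windows devote most of
the unit interval to the tissue class of interest, which is the intended
inductive bias.

## Network

A four-level residual 3D U-Net over feature widths (32, 64, 128, 256).
Encoder blocks are two zero-padded 3x3x3 convolutions
`c_in -> c_out/2 -> c_out` (the stem is `in -> 16 -> 32`) with an additive
shortcut; a 1x1x1 projection matches channels whenever the block changes
its width.  2x2x2 max-pooling sits between encoder levels.  Decoder
stages up-sample channel-preserving — either a stride-2 2x2x2 transpose
convolution (`transpose` mode) or trilinear up-sampling followed by a
zero-padded 3x3x3 convolution (`resize` mode) — concatenate the encoder
skip, and apply a residual block `concat -> mid -> c_out` with mid widths
(128, 72, 21).  Deep supervision attaches 1x1x1 classification heads to
the bottleneck and the two coarser decoder features; auxiliary class maps
are resampled trilinearly to full resolution and used only in training.
Class scores pass through a channel softmax, so outputs are voxel-wise
probability simplices.

The reference configuration uses plain biased convolutions and **no
normalisation layers**.  The reference model sizes for the four
configurations (one/three input channels x transpose/resize decoder) are

| input channels | decoder   | trainable parameters |
|---------------:|-----------|---------------------:|
| 1              | transpose | 4,896,693            |
| 3              | transpose | 4,897,621            |
| 1              | resize    | 6,530,997            |
| 3              | resize    | 6,531,925            |

and `count_trainable_parameters` reproduces all four exactly.  These
totals over-determine the outer structure and under-determine the block
interiors, so parts of the architecture are a reconstruction; the
reasoning is worth recording:

* The 928-parameter cost of going from one to three input channels equals
  `2 * (27*16 + 32)`, which pins a 3x3x3 stem `in -> 16`, a first-level
  width of 32, and a 1x1x1 input projection `in -> 32`.
* The 1,634,304-parameter cost of resize over transpose decoders equals
  `19 * (256^2 + 128^2 + 64^2)` (a 3x3x3 kernel has 19 more weights per
  filter pair than a 2x2x2 kernel), which pins three channel-preserving
  up-sampling stages at widths 256, 128 and 64 — hence four levels.
* All four totals are odd.  Every normalisation-bearing variant we
  enumerated (conv/bias/affine-norm combinations, one or two convolutions
  per block, conventional mid widths, 5/6/7-class heads, concatenative or
  projected-additive skips) yields even totals with even channel counts,
  so the reference model cannot contain affine normalisation layers with
  a conventional even-width scheme.  Plain biased convolutions match once
  two interior widths are solved from the totals.
* The remaining freedom was closed by keeping every block at its
  conventional width except the two finest decoder blocks, whose first
  convolution widths (72 and 21) are the unique pair completing this
  otherwise-regular scheme to all four printed totals simultaneously.

`norm_kind="instance"` (affine instance normalisation, the natural choice
at batch size one) is available for configurable variants and is used in
the scaled-down phantom training, where it markedly stabilises
convergence at the large initial learning rate.

Volumes whose spatial dimensions are not divisible by `2^(levels-1)` are
zero-padded symmetrically and un-padded on output, so phantom-sized
inputs need no manual padding.

## Numerical core

The network, losses and optimiser run on a small tape-based reverse-mode
autodiff engine over numpy arrays (`oarseg.nn`): stride-1 zero-padded
convolutions via im2col + BLAS, stride-2 transpose convolution, 2x2x2 max
pooling, trilinear 2x resampling as dense per-axis interpolation
matrices, affine instance normalisation, channel softmax, and the
elementwise/reduction ops the losses need.  Every backward pass is
analytic and validated against central finite differences in float64.
Activations default to float32; batch size is one volume throughout.

## Losses

With smoothed per-class soft Dice

    Dice_l = (2 * sum_V y_l p_l + 1) / (sum_V y_l + sum_V p_l + 1)

the three objectives are

* **wSD**: `sum_l w_l (1 - Dice_l)` with inverse-frequency weights at
  exponent `alpha = 1/3`;
* **wSD + XE**: the 1:1 linear combination (coefficients configurable) of
  wSD and the weighted cross-entropy
  `mean_x w_{l(x)} (-ln p_{l(x)}(x))`;
* **ExpLogLoss**: `mean_l (-ln Dice_l)^0.3 + mean_x w_{l(x)}
  (-ln p_{l(x)}(x))^0.3` with weights at `alpha = 0.5`.

Class weights are `w_l = f_l^(-alpha) / sum_k f_k^(-alpha)` over pooled
voxel frequencies of the training labels, background included, so they
sum to one.  The +1 Dice smoothing makes empty classes contribute a
perfect score and guards `-ln(0)`; probabilities are clamped to
`[1e-7, 1]` before logarithms.  The `x^0.3` derivative diverges at
`x -> 0`, so its gradient (not its value) is capped at `x = 1e-6`;
training otherwise NaNs whenever a voxel saturates to probability 1 in
float32.  Deep-supervision losses are aggregated as an equal-weight
normalised sum over the main and auxiliary outputs (configurable).

## Augmentation

Per training sample, independently: lateral mirroring (p=0.5), integer
voxel shifts up to ±4 voxels per axis (p=1; ±4 mm in-plane / ±10 mm
axially at 1x1x2.5 mm), rotations up to ±10° about the left-right and
cranio-caudal axes (p=0.75) imitating cervical flexion/extension and
axial rotation, and volumetric scaling in [0.90, 1.10] (p=0.5).  The
drawn transforms compose (mirror -> scale -> rotate -> shift, in physical
mm about the volume centre) into one affine resampling — tri-linear for
CT, nearest-neighbour for labels — so data is interpolated once.
Mirroring swaps the left/right parotid codes (`lr_label_pairs`,
overridable).  Identity draws return bit-identical copies.

## Training schedule

Adam (moments 0.9/0.999) from LR 1e-2; the LR divides by 10 whenever the
best validation loss stagnates for 100 epochs, training stops after 250
stagnant epochs or at 1000 epochs, and "improvement" means a decrease of
at least 1e-6 (absolute).  The plateau counter resets on decay and on a
new best; validation uses the configured loss without augmentation or
auxiliaries; the best-validation parameter state is checkpointed and
restored.  Gradient accumulation delays updates over 4 samples and
applies the mean gradient — by construction equal to the mean of
independently computed per-sample gradients at the fixed parameter state.
Cross-validation: 34 items over 5 folds gives test sets of 7/7/7/7/6
(every item tested exactly once) with 3 validation and the remaining
24 training items; an overlapping 5x7 variant is config-reachable.

## Phantoms

Synthetic cases (default 64x64x16 voxels at 1x1x2.5 mm; the phantom
geometry is expressed in shape fractions and scales to 200x200x56)
contain an air background, a soft-tissue head/neck
ellipsoid (~40 HU), and five organ solids with mm-realistic HU: axial
brainstem (35 HU) and thinner, more caudal spinal-cord (45 HU) tubes, a
bone-density mandibular arch (700 HU, anterior half-torus), and a
mirror-symmetric pair of lateral parotid ellipsoids (25 HU).  The cord
sits inside a vertebral canal — a CSF-density interior (12 HU) within a
bone-density tube (500 HU) concentric with it — because a cord floating
in uniform soft tissue would be almost invisible at this contrast-to-
noise, unlike the real cervical anatomy where the bony canal is the
dominant landmark; the canal is background anatomy (CT only, no label).
Gaussian noise (12 HU) plus mild smoothing (0.6 voxel) gives CT-like
texture.
Organ centres jitter a little between cases (parotids share one mirrored
jitter so the pair stays symmetric; a `symmetric()` spec disables jitter
entirely).  A simulated second observer warps each organ with an
independent smooth random displacement field whose maximum magnitude is
2 mm by default, producing per-organ DSC ~0.8–0.95 and mDTA ~0.1–0.4 mm
against the gold standard — the same order as inter-clinician deviation.

What the phantoms do **not** emulate: real anatomical shape variability,
contrast between adjacent soft-tissue structures as weak as in real neck
CT, streak/beam-hardening artefacts, and variable fields of view.
Passing the phantom training test therefore demonstrates that the
pipeline's mechanics (windowing, network, losses, schedule,
augmentation, metrics) are sound and can fit anatomy-like structure from
few samples — not that the model reaches clinical accuracy on real CT;
full-scale benchmark results require the external datasets and
GPU-scale training and are out of scope here.

## Evaluation

Boundary voxels are foreground voxels with a face-adjacent (6-connected)
background or out-of-volume neighbour.  The anisotropic Euclidean
distance transform of each segmentation is sampled on the other's
boundary voxels; the two directions are pooled, and summarised by their
mean (mDTA) and 95th percentile (HD95, linear-interpolation percentile).
Distances are voxel-centre to voxel-centre in mm.  DSC is also reported;
two empty masks give DSC 1.0 by convention, and organs empty on either
side get NaN distance metrics with the exclusion flagged.  Paired
observer comparisons use the two-sided Wilcoxon signed-rank test
(zero differences dropped; an all-zero difference vector returns
`(nan, 1.0)`).

## Scaled-down demonstration scale

The end-to-end training demonstration uses ten default-sized phantoms
(eight training, one validation, one held-out), the three-window input, a
reduced-width network (8/16/32 features, instance normalisation, deep
supervision) and the ExpLogLoss with the standard protocol compressed
(up to 110 epochs, plateau patience 30, gradient accumulation 4).  This
is the package's chosen demonstration size; it reaches DSC > 0.8 for all
five organs on the held-out phantom on a single CPU, with the thin
spinal cord and the brainstem the last to converge.

## Known limitations

* The block-interior widths (72, 21) are reconstructed, not independently documented;
  any scheme matching the four totals is observationally equivalent at
  the parameter-accounting surface.
* The anatomically consistent crop of the original pipeline used
  landmark-detection software that is external work; here the crop centre
  is explicit configuration (default: volume centre).
* DICOM ingestion and rescale handling are out of scope; inputs are
  assumed to be HU-calibrated NIfTI.
* The numpy engine is single-threaded apart from BLAS; it is sized for
  phantom-scale experiments, not for 200x200x56 training runs.
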