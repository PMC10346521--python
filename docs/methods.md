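# Methods

## The model

`leafnet` classifies RGB images of single leaves into nine classes, the
product of stalk position (lower / middle / upper) and ripeness stage
(under-mature / mature / over-mature). The classifier is a lightweight
convolutional network built from three pieces:

**Backbone.** A depthwise-separable convolutional stack: a 3×3 stride-2
stem to 32 channels followed by thirteen stages, each a depthwise 3×3
convolution and a pointwise 1×1 convolution, every convolution followed
by batch normalization and ReLU. The channel/stride schedule is the
standard one (64; 128/2; 128; 256/2; 256; 512/2; 512×5; 1024/2; 1024),
giving five natural resolution scales. A width multiplier scales every
backbone channel count; the pyramid width below is not scaled.

**Feature pyramid.** The pointwise-ReLU activations of stages 1, 3, 5,
11 and 13 are tapped as C1…C5 (spatial sizes 112, 56, 28, 14, 7 at a
224-px input; widths 64–1024). Each tap passes through a biased 1×1
lateral convolution to a common 64-channel width, and the pyramid is
fused top-down: P5 = lateral(C5), and Pi = lateral(Ci) + upsample×2(Pi+1),
with parameter-free bilinear upsampling (half-pixel centers) and
parameter-free elementwise addition. The classification head reads only
the fully fused, highest-resolution map P1; the coarser levels influence
it through the top-down path.

**Attention and head.** Spatial attention (a CBAM-style block: the
per-location channel mean and max maps are concatenated, passed through
a biased 3×3 convolution and a sigmoid, and the resulting H×W weight map
multiplies the features) is applied to P2 immediately before its fusion
into P1. Squeeze-excitation (global-average squeeze to a channel
descriptor; a bias-free two-layer bottleneck at ratio 32 with ReLU then
sigmoid; channelwise rescaling) is applied to the fused P1. The head is
BatchNorm → global average pooling → a dense softmax layer over the nine
classes.

Ablation variants — base (backbone only), +FPN, +FPN+SE, +FPN+SP, and
the full +FPN+SP+SE — are assembled from the same parts; the base
variant's head consumes the final 1024-channel backbone map directly.

### Parameter accounting

Parameter counts include non-trainable batch-norm moving statistics
(four numbers per normalized channel), matching the convention of the
reference deep-learning ecosystems. With the defaults this gives exactly
3,238,089 parameters for the baseline classifier and 3,357,276 for the
full variant; the difference decomposes as laterals Σ(ci+1)·64 = 127,296,
spatial-attention conv 3·3·2+1 = 19, squeeze-excitation 2·64·2 = 256,
head BatchNorm 4·64 = 256, and the 64→9 head replacing the 1024→9 one
(585 − 9,225). Several design details are pinned by this accounting:
fusion must be additive (parameter-free), upsampling bilinear
(parameter-free), laterals and the SP conv biased, and the SE bottleneck
bias-free at ratio 32. These choices are asserted term-by-term in the
test suite.

### Numerical choices

- All computation is float32 NHWC on an in-repo reverse-mode autodiff
  core (`leafnet.autodiff`): convolutions by im2col + BLAS matmul (1×1
  convolutions collapse to a single matmul), depthwise convolutions and
  their gradients by strided accumulation over the 3×3 footprint, batch
  normalization with momentum 0.9 and ε = 1e-3, bilinear resampling as a
  separable pair of sparse row-stochastic matrices. Every operator's
  gradient is verified against central finite differences.
- Weights are Glorot-uniform initialized from a per-model seeded
  generator. Glorot (rather than He) keeps the pre-sigmoid logits of the
  attention gates small at initialization — with He initialization the
  squeeze-excitation expansion layer (fan-in 2 at ratio 32 on 64
  channels) starts with unit-scale weights, its sigmoid gates saturate,
  and training stalls.
- Batch-norm momentum 0.9 (not 0.99) so that the moving statistics used
  at inference converge within the short training schedules the package
  targets; with momentum 0.99 the statistics are still near their
  initialization after a few hundred optimizer steps and validation
  metrics are meaningless.
- The channel-max reduction routes its gradient to the first maximizing
  channel on ties; tie inputs have measure zero under training noise.

## Training protocol

Categorical cross-entropy minimized for 30 epochs at batch size 32 by
default, with reduce-on-plateau: if validation loss has not strictly
decreased for `plateau_patience` (default 5) consecutive epochs the
learning rate is halved and the counter resets ("did not decrease" is
strict; ties count as non-improvement; minimal delta 0). Optimizers: SGD
(plain), RMSprop (ρ 0.9, ε 1e-7) and Adam (β 0.9/0.999, ε 1e-7), with
the 3×3 protocol grid {SGD, RMSprop, Adam} × {5e-3, 5e-4, 5e-5}
summarized by final-five-epoch mean validation accuracy and loss. No
weight decay, no dropout, no early stopping. Pretrained initialization
is deliberately absent: all experiments here train from random
initialization, which suffices on the synthetic data. Data order is
deterministic given the training seed; weight-level determinism across
platforms is best effort (BLAS reduction order), not a contract.

## Data pipeline

**Split.** 7:2:1 stratified: within each class of size n, training
receives round-half-to-even(0.7·n) items and validation
round-half-to-even(0.2·n), the remainder to test. Rounding is done in
exact rational arithmetic (0.7·25 = 17.5 → 18), which is the rule that
reproduces a 1,511-image training set from the nine reference class
counts (215, 298, 200, 248, 279, 194, 251, 255, 219; floor would give
1,507, half-up 1,513). Items are ordered by a content digest before the
seeded shuffle, so the split is invariant to input ordering.

**Augmentation.** Offline, training split only, sixfold: the original,
90° and 270° rotations, a horizontal mirror, a brightness rescale by
u ~ U(0.8, 1.2), and Gaussian pixel noise at σ = 0.02 — the four
standard label-preserving transform families, with the sixfold
multiplier chosen because 9,066 / 1,511 = 6. Right-angle rotations
rather than arbitrary angles keep the expansion deterministic and
artifact-free. Per-image randomness derives from (seed, index).

**Resize.** Bilinear to the model's input size, via the same
half-pixel-center separable-matrix resampler the pyramid uses, so the
whole system shares one interpolation convention (verified equivalent to
`skimage.transform.resize(order=1, anti_aliasing=False)`).

## Synthetic data

Field photographs for this task are not publicly available, so the
package generates leaf-like scenes that carry the same label structure
and decision cues: an elliptical blade whose hue encodes ripeness
(green ≈ 0.33 → yellow-green ≈ 0.20 → yellow-brown ≈ 0.10 in HSV hue,
with necrotic spots on over-mature blades), whose size and aspect encode
stalk position (semi-major axis 0.44 / 0.33 / 0.24 of the image for
lower / middle / upper), with a dark midrib and oblique secondary veins,
over a soil-textured background with weed-like green clutter blobs
(count ∝ `clutter_level`). Blades are rendered brighter than the soil so
the leaf outline — the position cue — remains recoverable even for
yellow-brown over-mature blades, which are otherwise nearly iso-color
with soil. Default per-class counts mirror the nine reference counts
(sum 2,159). Everything is deterministic given (class, seed, size).

Two variation regimes exist: `"field"` (default) jitters geometry and
color the way field photographs vary; `"low"` (exposed as
`easy_config()`) nearly freezes the nuisance parameters and removes
clutter, giving the deliberately easy regime used for smoke training.
What the generator does **not** model: illumination direction and
shadows, perspective and pose, camera optics, leaf damage other than
spots, occlusion by other plants. Tests passing on this data therefore
demonstrate that the architecture, pipeline and training loop function
and can extract color/shape/texture signal — not field-level accuracy.

## Problem sizes for the built-in experiments

The package's own verification runs are sized for a single CPU: the
smoke-training check trains the quarter-width 96-px full variant for ten
epochs on the easy regime with 80 images per class (7:2:1 split), batch
size 4, Adam at 5e-3 with plateau patience 2, and takes the median final
validation accuracy over three seeds. The small batch trades batch-level
parallelism for optimizer steps inside the fixed ten-epoch budget, and
the reactive patience plays the role the default patience 5 plays on a
30-epoch schedule. The ablation check trains all five variants for one
epoch on the same set. The 3×3 optimizer grid is exercised at toy scale
for bookkeeping; its full-scale protocol values remain the defaults.

## Robustness harness

Three perturbation families emulate field conditions: additive Gaussian
noise (σ in normalized [0,1] pixel units; grid values 0.1 and 0.5),
multiplicative brightness change (0.8 and 1.2), and occlusion by a
single black axis-aligned square whose side is round(√(ratio·H·W)) (area
ratios 0.3 and 0.5), each applied to a class-stratified random subset of
the evaluation set (30%, 70% or 100%) after resizing, with the rest left
intact; the model classifies the union and per-class accuracy is
tabulated. The subset reading of "proportion" (perturb a fraction, keep
the rest) was chosen over mixing perturbed copies into the set; the
square-at-ratio occluder is the simplest faithful reading of an
"occlusion ratio".

## Explanations

Score-CAM: for a chosen layer (default the final pre-pooling feature
map), each activation channel is bilinearly upsampled to input size,
min-max normalized to a soft mask (a constant channel becomes an all-zero
mask), multiplied into the input, and forward-passed; a softmax over the
target-class scores of these masked inputs weights the channels, and the
heatmap is the min-max-normalized ReLU of the weighted channel sum. The
procedure is gradient-free by construction and the implementation runs
entirely in inference mode; results are independent of the masking batch
size. The plain-score softmax weighting (no baseline subtraction) is
used. The max-activation overlay takes the per-position channel maximum,
upsamples, normalizes and alpha-blends (default 0.5) a jet-style
colormap with the input, warm colors marking strong response.

## Known limitations

- Trained accuracy on real field imagery is out of reach by design; the
  synthetic regime measures machinery, not agronomy.
- The NumPy training core is single-threaded BLAS-bound; it is suited to
  the package's small-scale experiments, not to full-scale training.
- SGD is momentum-free; optimizer hyperparameters beyond the learning
  rate follow common ecosystem defaults.
- Checkpoints store raw weight arrays (npz + JSON sidecar); no format
  migration is promised across versions.
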