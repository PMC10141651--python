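# Methods

## The model

`fusionseg` implements a multi-modal residual encoder–decoder for 2-D
brain-tumor MRI segmentation with two distinguishing mechanisms: a hybrid
attentional fusion block (HAFB) in every skip connection, and a masked
dual-branch self-supervised pretext task trained jointly with the
segmentation objective.

**Backbone.** Each of the four MRI modalities (T1, T1CE, FLAIR, T2) has its
own encoder of `n_layers` (default 4) residual stages

    Conv(x)    = ReLU(BN(conv3x3(x)))
    ResConv(x) = conv1x1(x) + Conv(Dropout(Conv(x)))
    EL(x)      = MaxPool2x2(ResConv(x))

so a 224x224 slice reaches a 14x14 bottleneck (1/16 of the input side).
Encoder stage *l* outputs `base_filters * 2^l` channels (32, 64, 128, 256
with defaults). Each modality's bottleneck map passes through an atrous
spatial pyramid (ASPP): parallel dilated 3x3 convolutions at rates
(1, 6, 12, 18) plus a global-average-pooled 1x1 branch, concatenated and
projected back to the input width. The per-modality ASPP outputs are
concatenated and merged by one more ResConv; the decoder then alternates
2x2-stride-2 transposed convolutions, concatenation with the skip bundle of
the matching encoder level, and a ResConv, ending in a 3x3 convolution to
the four class scores.

**Hybrid attentional fusion.** At every skip level the n per-modality maps
(C channels each) are reduced elementwise three ways — sum, product, and
maximum — and concatenated into a 3C-channel map F, independent of n. A
soft-attention gate

    HAFB(F) = conv3x3( F + F * sigmoid(conv3x3(ReLU(conv3x3(F)))) )

(squeeze 3C→C, restore C→3C, sigmoid) reweights F before a final 3x3
mixing convolution. Because the fused width is pinned at 3C, decoder size
does not grow with the modality count; without the block, the skip bundle
is the plain concatenation of the n maps and the decoder widens
proportionally.

The fused reductions are computed over elementwise-*sorted* operands, so
the output is bit-identical under any permutation of the modalities (naive
float accumulation would differ in the last ulp). The running product is
clipped to 1e4 in magnitude to prevent float32 overflow for many
modalities.

**Parameter scaling.** With the channel plan above the total learnable
count is exactly affine in the modality count n with HAFB and exactly
quadratic without it (the merge and decoder widths carry the factor n).
At the reference width (base 32) the fusion variant is larger for n ≤ 2
and smaller for n ≥ 4 — fusion costs attention parameters at few
modalities and saves decoder parameters at many. These scaling *laws*, not
any absolute count, are the tested contract: the literature's absolute
counts depend on ASPP and decoder widths that are not part of this
package's published plan.

**Self-supervision.** Each training batch is forwarded twice through the
*same* encoders: once clean, once with every modality occluded at its own
window position (positions pairwise distinct, so the unmasked modalities
carry the missing information). Four occlusion geometries are provided —
one 20x20 square (400 px), one 50x50 square (2500 px), sixteen 5x5 squares
on a 10-px period inside a 35x35 window (400 px), and 400 random pixels
inside a 35x35 window. The pretext loss is one minus the smoothed cosine
similarity (epsilon = 1e-5) between the two branches' concatenated
post-ASPP bottleneck features; the decoder consumes only the clean branch.
A printed variant of this loss without the square root in the denominator
does not vanish for identical branches; the cosine form is the default and
the literal form is available behind `literal=True`.

**Objective.** Per batch of M samples,

    L_seg   = (1/M) * sum_i ( alpha * L_dice_i + beta * L_ce_i ),  alpha=1, beta=0.5
    L_total = L_seg + lambda_sim * L_similarity

with soft class-mean Dice (smoothing 1e-5, background class included by
default) and per-pixel cross-entropy. The batch normalizer M is taken as
batch size; a class-mean reading of the same formula is configurable.

## Evaluation

Predictions are scored on the three nested BraTS regions — whole tumor
WT = {1, 2, 4}, tumor core TC = {1, 4}, enhancing tumor ET = {4} (raw
encoding) — with Dice, sensitivity, specificity, and HD95. HD95 is the
95th percentile of the pooled symmetric boundary-distance distribution
(Euclidean pixel metric, 4-neighbour boundaries, both directed distance
sets pooled before the percentile, which makes it symmetric). An
empty-vs-empty region scores Dice 1 / HD95 0; empty-vs-nonempty scores
Dice 0 and an HD95 penalty defaulting to the image diagonal.

## Preprocessing conventions

BraTS volumes are 240x240x155 with labels {0, 1, 2, 4}. The pipeline keeps
the centered 144 axial slices (third array axis; offset floor((D-144)/2),
so depth 155 keeps indices 5..148), center-crops to 224x224 (offset
floor((S-224)/2)), remaps label 4 to the contiguous internal value 3, and
z-scores each slice and modality over its nonzero (brain) pixels, leaving
background at exactly 0. Neither the window offset nor the normalization
is dictated by the data format: the offset convention is this package's
choice, and per-slice z-scoring is the conventional BraTS treatment; both
are plain functions that callers can replace. Slices with an empty brain
mask are kept. Predictions are written back in the raw encoding, zero-
padded to the original frame.

## The phantom generator

Phantoms exist so the whole method is exercisable and testable without any
data download. A case is a brain-shaped disc (radius 0.42 x side) on a
zero background with a nested tumor: an edema ellipse (class 2) containing
a core ellipse (class 1, 0.62 x linear scale) containing an enhancing blob
(class 3, 0.32 x), all jittered and rotated, sized so the tumor occupies a
requested fraction of the image (default 5–15%, verified by pixel count
with seeded rejection). Each modality renders the same geometry with its
own class-mean table plus Gaussian noise (sd 0.05): the means are chosen
so that within every modality at least one class pair is (near-)
isointense — enhancing tumor with brain on T1, edema with brain on T1CE,
core with enhancing on FLAIR/T2 — while across modalities all classes
separate. Multi-modal fusion is therefore genuinely informative on
phantoms, not decorative.

What phantoms do *not* emulate: anatomy, bias fields, partial-volume
effects, registration error, 3-D tumor continuity, or class-imbalance
statistics of real gliomas. A passing phantom suite shows that the
implementation is correct and trainable, not that real-data scores
transfer.

## Numerical and training choices

- All arithmetic is float32 on a compact tape-based numpy autograd written
  for this package (stride-1 dilated conv, 2x2 transposed conv and
  max-pool, batch-norm, softmax/CE; each backward pass is hand-written and
  finite-difference-tested). Convolution gradients are computed per kernel
  offset with batched BLAS matmuls, which keeps peak memory near the
  activation footprint.
- Convolutions followed by batch-norm carry no additive bias; the 1x1
  residual projections, attention convolutions, and the final class
  convolution do. Transposed convolutions are bias-free. Max-pool ties take
  the first maximal element; fusion-maximum gradient ties route to a
  single operand.
- Dropout rate defaults to 0.2 (the layer's placement is fixed between the
  two convolutions of ResConv; the rate is not externally prescribed).
- Optimizer defaults mirror the training protocol this architecture is
  published with: Adam, batch 8, initial lr 1e-5 decaying by 0.9 every 5
  epochs (0-based, first decay at epoch 5), 15 epochs. These defaults are
  tuned to GPU-scale training over tens of thousands of slices. The
  package's own desk-scale smoke runs (200 training slices of side 64,
  base_filters 8, 10 epochs — a few CPU-minutes) use lr 1e-3: at a few
  hundred optimizer steps the published rate would barely move the
  weights, and the phantom task is intensity-separable, so a larger step
  size is the appropriate scale equivalent. Those smoke runs reach
  held-out whole-tumor Dice ≈ 0.99 with the similarity loss falling
  monotonically.
- Training is deterministic given the seed (single-threaded BLAS, seeded
  phantom/mask/shuffle/dropout streams), up to floating-point reduction
  order inside BLAS.
- Mask fill value is 0, the post-normalization background level.
- The masked branch is compared post-ASPP (where the two branches meet
  ahead of the merge); comparing pre-ASPP features is a one-line change in
  `dual_branch_forward`.

## Known limitations

- 2-D slices only; no 3-D convolutions or volume-context modelling.
- Absolute parameter counts of published reference tables are not
  reproduced (under-specified widths); only their scaling structure is.
- The BraTS online portal's exact evaluation protocol (case exclusions,
  tie-breaking) is not replicated; `evaluate` implements the standard
  definitions above.
- The phantom generator's simplicity means phantom Dice scores say nothing
  quantitative about BraTS Dice scores.
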