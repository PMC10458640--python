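# Methods

This note documents the model, the numerical choices, the synthetic data
generator and the open design points that were settled while building the
package. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The model

Polyps are raised mucosal growths whose colour and texture often barely
differ from the surrounding tissue; their size in public benchmarks spans
from a handful of pixels (ETIS) to a third of the frame (Kvasir-SEG).
Plain encoder–decoder CNNs localize them well but miss global context;
full self-attention supplies that context at quadratic cost. The network
implemented here takes a third route: a per-channel *gate* computed by a
stack of large-kernel depthwise + 1×1 convolutions over the decoder's
global feature map.

The forward path is: pyramid encoder (strides 4/8/16/32) → feature
enhancement of the three deepest levels → partial decoding into a stride-8
global map `G` with `C_g = 64` channels → mixing module → channelwise gate
→ 1×1 mask head. Components:

* **Encoder.** The default is PVTv2 at b2 capacity (embedding dims
  64/128/320/512, depths 3/4/6/3, SRA ratios 8/4/2/1, overlapping patch
  embeds), implemented directly on the package's autodiff core. The b2
  variant is an assumption: it is the capacity its closest comparator
  systems use; the choice is configurable. Pretrained ImageNet weights are
  not bundled — the builder accepts an `.npz` state dict; all tests use a
  seeded 4-stage strided-conv `tiny_test` encoder that satisfies the same
  pyramid contract.
* **FEB.** The published description derives the block from receptive-field
  blocks "with added dilation rates" but does not fix the branch layout.
  We adopt the layout standard in the polyp-segmentation lineage: a 1×1
  branch plus three branches of 1×1 → (1×k, k×1) factorized kernels
  (k = 3, 5, 7) → 3×3 with dilation 3/5/7, concatenated, fused 3×3, plus a
  1×1 shortcut and ReLU. The dilation list is configurable (an extra rate
  appends a fourth branch with the next odd kernel); per-branch effective
  receptive fields are strictly increasing by construction
  (`FEB.receptive_fields()`). Batch norm is used inside branches by
  default, with a norm-free variant for batch-size-1 inference.
* **PPD.** The cascaded partial-decoder topology: deeper maps are
  upsampled, refined by 3×3 convs, multiplied into shallower maps, then
  progressively concatenated and fused. The "modified" fusion conv carries
  a configurable dilation (default 2). Output channels equal `C_g`.
* **Mixing module.** Patch embedding is `LN(GELU(Conv(k=p, stride=p)))`
  after reflect-padding to a multiple of `p`; the activation is GELU to
  match the mixing blocks. Each of the `depth` blocks applies the two
  residual-normalized halves given in the README; layer normalization (over
  channels, per spatial site) is used throughout the module, never batch
  norm. The final token grid is average-pooled and squashed by a sigmoid
  into one weight per channel.

  The printed hyperparameters (depth 20, dim 64, kernel 28, patch 9) are
  only mutually consistent if the module operates at the *input* resolution:
  at stride 8 a 44×44 map patched by 9 gives a 5×5 token grid, far smaller
  than the 28-kernel. The default therefore bilinearly upsamples `G` to the
  input size (352 → pad 360 → 40×40 tokens) before embedding; a `stride8`
  mode is retained with the kernel clamped to the token-grid size. The
  even 28-kernel uses asymmetric (13, 14) "same" padding.

  The gate is read as a per-channel scalar vector ("per channel weights");
  a spatial-map reading exists but is not implemented. `dim = C_g` is
  enforced by the default configuration; if a user sets them apart, a 1×1
  input adapter and a linear gate projection bridge the mismatch.
* **Mask head.** The architecture description ends at the gated map; the
  1×1-conv → bilinear-upsample → sigmoid head is this package's own
  plumbing and is labelled as such in the code.

## Loss

`L = L_BCE + L_IoU` with the printed sum-form available as
`reduction="sum"` (used by all oracle tests) and a `"mean"` form for
optimization (BCE per pixel, IoU per image then per batch) so gradient
scale is independent of image and batch size. Probabilities are clamped at
1e-7 before logs. The degenerate all-background/all-zero IoU ratio returns
0 (perfect) with a warning. A pixel-weighted ("hard-pixel") variant was
deliberately not implemented: the printed equations are unweighted.

## Metrics

Dice and IoU binarize at 0.5 by default (the dominant convention in the
comparator code bases) with an adaptive 2×mean option; ground-truth PNGs
binarize at 128/255. The weighted F-measure follows the reference
algorithm (β²=1, 7×7 Gaussian of σ=5, exponential distance weighting with
the log(0.5)/5 constant) with two deliberate refinements, chosen so the
measure is exact at the frame boundary and reproducible to 1e-6 against a
loop oracle:

* the error-spreading convolution uses *symmetric* boundary handling
  (zero padding would let border foreground pixels of an inverted
  prediction score above 0);
* nearest-foreground ties in the dependency step follow the exact
  Euclidean feature transform's deterministic convention.

The S-measure implements the object + region decomposition (α=0.5,
centroid-split quadrants, the reference's degenerate-map conventions). The
E-measure maximizes the enhanced-alignment score over 256 uniform
thresholds; it is normalized by `N` rather than the reference's `N−1` so a
perfect prediction scores exactly 1 and the measure stays inside [0, 1]
(the difference is < 1e-5 at benchmark resolutions). Aggregation is the
arithmetic per-image mean; images whose empty ground truth makes `Fβω`
undefined are excluded from that column with a warning.

## Training recipe

Defaults follow the published setup: 352×352 inputs, batch 16, 60 epochs,
Adam at 1e-4, polynomial decay, multiscale factors {0.75, 1, 1.25} drawn
per batch with sizes snapped *up* to the nearest multiple of 32 (the
encoder contract; snapping up avoids shrinking the scale range), rotation
up to ±90° and horizontal/vertical flips applied identically to image and
mask, ImageNet normalization. "Polynomial decay with factor 0.1" is
ambiguous; the default is the standard poly schedule `(1 − e/E)^0.9`, with
a step ×0.1 alternative in the config. Adam β's are library defaults, as
none are published. One integer seed drives weight init, shuffling,
augmentation and scale draws, so identically seeded runs produce identical
loss curves; checkpoints round-trip bitwise.

The `tiny` preset (96px inputs, tiny encoder, FEB/PPD width 16, mixer
depth 2 / dim 16 / kernel 7 / patch 4) exists for CPU-scale smoke and
overfit runs; it uses full-batch Adam at 5e-3 with a gentle poly decay
(power 0.3), which suits a 169k-parameter model memorizing a handful of
images. Train/val splits for the real benchmarks are supplied by the user
as directory manifests; no split is hard-coded.

## Synthetic data

The generator emulates the statistical structure of the benchmark corpora:
1–3 rotated super-ellipses with smooth random radial perturbation, areas
log-uniform over (0.002, 0.25) of the frame (ETIS-like specks through
Kvasir-like masses), foreground colour equal to the background texture
shifted by a contrast delta that may be near zero (the hard
polyp-vs-mucosa case), Gaussian-blurred transitions, additive specular
disks, multiplicative vignette, and crisp {0, 255} masks. Every sample is
a pure function of `(seed, index)`; the manifest stores blob geometry so
masks re-render bit-for-bit. What it does *not* emulate: real mucosal
texture statistics, instrument artefacts, motion blur, or the label noise
of human annotation — so green tests demonstrate that the pipeline
optimizes, evaluates and reproduces correctly, not that the trained toy
model generalizes to colonoscopy imagery. For the same reason the
acceptance script reports train-set metrics of the deliberately overfit
toy model rather than held-out numbers, which at this scale mostly measure
the generator's difficulty.

## Ablation lattice

The cumulative chain backbone → +FEB1 → +FEB2 → +FEB3 → +FEB123+PPD → full
is reconstructed as configurations. "FEB1/2/3" are read as the first,
second and third FEB instances (on S2/S3/S4); the alternative reading of
FEB1 acting on S1 is available via `feb1_on_s1`. Rows without the PPD sum
all available maps (a 1×1+BN projection of S4 plus any FEB outputs,
bilinearly resized) at stride 8, which keeps every combination of ablation
flags runnable; the PPD row replaces that projection with the decoder.
`analytic_param_deltas()` derives each step's expected parameter increment
from kernel/channel arithmetic alone (the PPD step accounts for both the
added decoder and the removed projection), and tests assert the built
models match it exactly. Disabling the mixer is equivalent to a constant
all-ones gate feeding the same mask head.

## Numerical core

The autodiff engine is float64 throughout (reproducibility and tight
finite-difference checks outweigh speed at these problem sizes).
Convolutions use im2col + BLAS matmul, except stride-1 depthwise
convolutions with kernel area ≥ 64 — the mixer's spatial-mixing convs —
which run via FFT (forward, input-gradient and weight-gradient all in the
frequency domain); im2col would materialize k² copies of the token grid.
Backward passes recompute im2col buffers instead of caching them, bounding
peak memory. Bilinear resizing is expressed as two interpolation-matrix
multiplications (PyTorch-style `align_corners=False` coordinates), making
its transpose the exact gradient. Gradient-checking tests cover every op,
including the FFT and asymmetric-padding paths.

## Known limitations

* No GPU path and no multi-process data loading; the full-scale
  configuration trains far too slowly on CPU for benchmark reproduction —
  the package targets correctness, inspectability and scaled-down
  experiments.
* Pretrained PVTv2 weights must be converted to `.npz` by the user; no
  converter is bundled.
* The deep-supervision side output some related decoders use is not
  implemented (the training loss here is single-term by design).
* Whether the published kernel/patch sizes (28, 9) might be transposed
  cannot be resolved from the text; both orderings are one config edit
  apart.
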