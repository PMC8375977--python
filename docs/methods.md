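# Methods

## Model

MoNet is an encoder-decoder segmentation network for single-channel 2D
slices. The encoder applies a stem conv block (1 → f1 channels), then
alternates RDDC feature blocks with stride-2 convolutions (f1 → f2 → f3),
stopping after two down-samples so a 256x256 input keeps a 64x64
bottleneck. The decoder mirrors this with transposed-conv blocks
(f3 → f2 → f1), concatenating the matching encoder features and fusing
them with a 3x3 conv block before each decoder RDDC block; a 1x1
convolution with a sigmoid produces per-pixel foreground probabilities.

A *conv block* is convolution (with bias) → batch normalization → ELU.
An *RDDC block* stacks four such blocks at dilation rates 4, 3, 2, 1, each
followed by spatial dropout (whole feature channels dropped), wrapped in a
residual short connection. Each 3x3 convolution at dilation d adds 2d
pixels of receptive field, so one RDDC stack spans 1 + 2(4+3+2+1) = 21
pixels at unit stride — multi-scale context without extra parameters,
which is the design's premise for small, low-contrast targets.

The baselines are classic 4-down/4-up U-Nets with two normalized conv
blocks per stage, 2x2 max pooling, 2x2 transposed convolutions (bias, no
normalization), concatenation skips and a 1x1 sigmoid head, at 16 or 64
base filters with channel doubling per stage.

All layers, backprop and the Nadam optimizer are implemented in numpy
inside the package (`monetseg.nn`); gradients are validated against
central finite differences in the test suite (relative error < 1e-6 on
float64 layers).

## Parameter accounting and width resolution

"Parameter count" includes batch-norm running statistics: 4 parameters per
normalized channel (scale, shift, running mean, running variance). Under
this convention, with bias on all convolutions and bias-only 2x2 up-convs,
the baseline totals are integer-exact: U-Net-16 = 1,946,705 and
U-Net-64 = 31,054,145.

MoNet's published total is 403,556, but the per-stage widths are not
published. `resolve_monet_widths` enumerates a structural search space and
returns exact matches plus nearest misses. Two spaces are defined:

- the **ratio-constrained default** (f1 ∈ [12, 32], f2/f1 and f3/f2 ∈
  {1.5, 2}, up-kernel 2x2/3x3, optional second stem and fuse blocks,
  identity vs 1x1-projection residuals, normalized or plain up-blocks).
  It contains **no** exact match; the closest is 404,083 at widths
  (18, 36, 72).
- the **extended space**: the same structural grammar with free integer
  widths constrained to be strictly increasing and at most doubling per
  stage (f1 < f2 ≤ 2 f1, f2 < f3 ≤ 2 f2). It contains exactly one match:
  widths (20, 39, 66), 3x3 transposed convolutions in normalized up-blocks,
  and 1x1-projection residuals in the RDDC blocks, totalling 403,556.

That unique configuration is frozen as the canonical MoNet
(`configs/monet.yaml`). The package reports the count by building the
network and summing its registered tensors; a closed-form walk of the same
grammar is used only to make the search cheap and is cross-checked against
built networks in the tests.

## Training recipe

- **Loss**: soft Dice, `1 − (2Σpt + ε)/(Σp + Σt + ε)` summed over the
  batch, ε = 1e-6 (numerical safety without biasing small masks).
- **Optimizer**: Nadam with the standard moment defaults (β1 = 0.9,
  β2 = 0.999, eps = 1e-7) and initial rate 5e-4.
- **Schedule**: divide the rate by 10 when the best validation loss has
  not improved for 2 consecutive epochs; the stagnation counter resets
  after each decay. The recorded learning-rate trace is exactly
  reproducible from the validation-loss trace by replaying this rule.
- **Convergence**: "trained to convergence" is operationalized as stopping
  when a third decay would trigger, i.e. the rate has already decayed
  twice and validation loss stagnated for a further patience window.
- **Initialization**: uniform He — conv weights uniform on
  ±sqrt(6/fan_in) with fan_in = in_channels·kh·kw, zero biases, unit
  batch-norm scale; deterministic per seed.
- **Augmentation** (training batches only): rotation up to ±10°, zoom in
  [0.75, 1.25], shifts up to ±0.2 of the image side; images interpolated
  bilinearly, masks by nearest neighbour so they stay binary;
  out-of-bounds pixels take the slice minimum (masks take background).
- **Batch size** 32 by default, matching the timing protocol; configurable.

The *overfit harness* (`fit_fixed_batch`) is a convergence property check,
not the full recipe: a narrow MoNet (widths 4/8/16, dropout off, no
augmentation) trained full-batch on 8 fixed 128x128 phantom slices. It
uses a higher rate (5e-3) than the recipe's initial 5e-4 because
full-batch descent on a handful of fixed slices tolerates and needs a more
aggressive step; it reaches a training soft-Dice score of 0.95 well within
300 steps.

## Data pipeline

NIfTI image/label pairs are loaded slice-major with header spacing
preserved. Images are resampled bilinearly to the working resolution,
label grids with nearest neighbour (preserving integer values and
binarity), multi-organ labels are merged to a single foreground class, and
slices are z-score normalized per slice by default (modality-agnostic; a
clip+min-max windowing scheme is available). Splits are at the patient
level — train size = round(0.7·n), deterministic per seed, with a hard
no-leak assertion. Slice selection for training offers a "balanced" mode
(all foreground slices plus an equal number of random background slices)
and an "all" mode; which regime a given study used is generally not
recoverable, so both are exposed.

## Synthetic phantoms

The generator emulates the geometry and statistics that make abdominal
small-organ segmentation hard: a smoothly varying background field plus
Gaussian noise (sd 1.0), and an elongated foreground blob (2–4 overlapping
ellipses strung along a random curve) covering 0.5–3% of pixels with a
mean intensity offset of 3 noise-sd by default. Volumes are slice-coherent
(the blob drifts a bounded amount per slice) and can carry multi-integer
labels {1, 2} to exercise label merging. Everything is bit-deterministic
given (seed, config).

What the phantoms do **not** model: CT/MRI acquisition physics, organ
context and confusable neighbouring structures, inter-patient anatomical
variability, annotation noise. Passing the phantom suites therefore
demonstrates that the architecture, losses, pipeline and metrics are
implemented correctly and that the training loop converges — it says
nothing quantitative about segmentation quality on clinical data, and the
published external-data Dice/Hausdorff tables are deliberately not
reproduction targets here.

## Metrics

Dice is 2|A∩B|/(|A|+|B|); defined as 1 when both masks are empty (flagged)
and 0 when exactly one is. The Hausdorff distance is the symmetric max of
directed nearest-neighbour distances between foreground voxel sets
(KD-tree implementation, brute-force-verified), computed in voxel units by
default with optional physical spacing, with an optional percentile
variant (e.g. HD95); it is undefined for empty masks and reported as such
rather than skipped. Published Hausdorff magnitudes of ≈1.8–2.1 for this
task family imply an unstated normalization or unit; the package does not
guess it — it exposes the max and percentile variants and documents the
ambiguity. Per-patient evaluation binarizes slice probabilities at 0.5,
stacks them in acquisition order and computes both metrics on the 3D
volumes.

## Efficiency analyses

Serialized weights use a `.monet` container: an 8-byte magic, a JSON
manifest (tensor names, shapes, trainability, architecture descriptor) and
a little-endian float32 payload of exactly 4 bytes per counted parameter;
round trips are bit-exact and sizes are reported in binary megabytes
(canonical MoNet: 1.55 MB, manifest overhead < 2%). CPU timing uses a
monotonic clock over 150 images of 256x256 with 5 repetitions and an
excluded warm-up pass; absolute times are hardware-bound, carry an
environment descriptor and are never treated as comparable across
machines. Activation analysis captures post-activation tensors at tagged
early/middle/late layers (capture is observationally transparent),
histograms them over 64 uniform bins spanning the observed range, and
reports the near-zero fraction |a| < τ with τ = 1e-3 by default (the
collapse threshold is a convention, hence configurable). Which concrete
layers count as early/middle/late is configuration, with defaults
(stage-1 RDDC, bottleneck RDDC, last decoder RDDC for MoNet).

## Numerical choices and degenerate inputs

- float32 weights and activations; float64 accumulation in loss/metric
  reductions; optimizer moments in float64.
- 'same' padding everywhere (asymmetric where needed) so spatial sizes are
  exactly 256/128/64; transposed convolutions are realised as
  zero-insertion + convolution and always produce stride × input size.
- Batch norm: eps 1e-5, running-statistic momentum 0.9; inference uses
  running statistics.
- Spatial dropout rate 0.1 (conventional; it has no effect on parameter
  counts and is disabled at inference and in the overfit harness).
- z-score normalization guards zero variance; Dice guards empty masks as
  above; the affine augmentation of an all-background mask stays
  all-background by construction (constant fill 0).
- Non-finite training loss aborts with a diagnostic rather than continuing.

## Problem sizes

The shipped defaults are desk-scale by design: phantoms default to 16
patients × 8 slices at 128x128 (256x256 available), the test suite trains
narrow-width MoNets (2–16 channels) on 32–128 px slices, and the overfit
harness uses 8 slices at 128x128. These sizes were chosen so a complete
run is a coffee-break affair on one CPU core while still exercising every
code path at full 256x256 geometry where the contracts demand it
(bottleneck and output-shape checks run at 256x256).

## Known limitations

- 2D only; no 3D convolutions, ensembling or attention-gated baselines.
- The numpy backend is single-threaded except for BLAS matmuls; it is
  built for correctness and desk-scale experiments, not for GPU-scale
  training.
- The canonical width configuration (20, 39, 66) is the unique exact match
  of the documented structural grammar, but the grammar itself is a
  reconstruction; other graph layouts could reach the same total with
  different widths.
- Hausdorff values are reported in voxel (or physical-spacing) units; no
  attempt is made to match normalizations that cannot be inferred.
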