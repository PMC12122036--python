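# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish.

## Numerical engine

The package carries its own reverse-mode autodiff engine
(`defifnet.autodiff`) over numpy arrays: a tape of primitive operations
(elementwise arithmetic, activations, reductions, channel
slicing/permutation, stride-1 "same" grouped convolution, 2×2 max pooling,
×2 bilinear upsampling with corner alignment off, batch/group
normalization) with closures propagating gradients. Convolutions are
computed by im2col + matrix multiplication; the backward pass reuses the
same kernel with flipped, channel-swapped weights, which is exact for odd
kernels at stride 1. Every primitive's gradient is checked against central
finite differences in `tests/test_autodiff.py`. Weights use fan-in-scaled
(Kaiming) normal initialization from an explicit seeded generator; all
computation is float32, with float64 used only in test oracles.

## Architecture

Per encoder level i with width c_i:

    left_i  = ConvBNReLU3x3(ConvBNReLU3x3(left_{i-1}))
    gdf_i   = Conv7x7(gdf_{i-1})                    (plain conv + bias)
    fused_i = FIFConv(left_i + gdf_i)
    skip_i  = CFRM(fused_i)
    left_{i} -> maxpool 2x2 -> next left level
    fused_{i} -> maxpool 2x2 -> next GDF level

After L = 4 levels the two pooled streams are merged by elementwise
addition, then bottleneck = ConvBNReLU3x3 → ConvBNReLU3x3 → MBGM. Decoder
level (deepest first): bilinear ×2 upsample, 1×1 channel adjustment,
concatenation with the skip, two ConvBNReLU3x3 producing F1, output
FIFConv(F1) + F1. Head: 1×1 convolution + sigmoid (softmax for more than
one class).

Open points resolved during assembly, kept as the package's own choices:

- **FIFConv channel widths.** Splitting C channels into halves and ending
  with one elementwise sum only returns C channels if the per-half 1×1
  convolutions lift C/2 → C; the concatenated gate stage then carries 2C
  channels and its re-split halves C each. This is the minimal reading that
  preserves the declared input/output shape.
- **FIFConv gating granularity** is global spatial average pooling — one
  scalar per channel, broadcast multiplicatively (squeeze-style gating).
- **CFRM branch 2** uses a grouped 3×3 convolution (group count 2) and
  group normalization with 2 groups, non-affine — the learnable scale/shift
  pairs are the explicit zero/one-initialized parameters, so at
  initialization both branch gates equal sigmoid(1) ≈ 0.7311.
- **MBGM wiring.** Z = C3( C1(C1(Y)) ‖ (C1(Y) + C3(C1(Y))) ) with a single
  shared primary 1×1 path: the ghost half is the cheap second 1×1, the
  extra 3×3 branch taps the primary path and is fused residually before the
  exit convolution. BN+ReLU follows every MBGM convolution.
- **Normalization placement.** FIFConv and CFRM convolutions are plain
  conv + bias, exactly as their defining expressions state (a `fif_norm_act`
  flag can add BN+ReLU). The standard U-Net-style 3×3 units of the encoder,
  bottleneck and decoder use conv-BN-ReLU — conventional for this
  architecture family and necessary for stable full-batch optimization; the
  counters include these BN affine parameters.
- **Downsampling** is 2×2 max pooling, stride 2; **upsampling** is
  parameter-free bilinear interpolation, consistent with the tiny parameter
  budget. The two encoder streams stay separate between levels (the GDF
  stream propagates the pooled fused maps) and merge once, additively, at
  the bottleneck.

## Channel-schedule calibration

The published description fixes the topology but not the per-level widths.
`scripts/calibrate_channels.py` searches doubling schedules (b, 2b, 4b, 8b)
with bottleneck c_L or 2c_L first; none meets the published budget of
0.24 M parameters / 0.33 G MACs at 256×256 (the closest are 0.17 M/0.39 G
and 0.33 M/0.43 G), and base width 6 is excluded because the grouped
convolutions require widths divisible by 4. The search therefore widens to
all non-decreasing multiples-of-4 schedules up to width 64 with a free
bottleneck in [c_L, 2c_L]: exact analytic parameter counts prescreen
candidates, MACs are then measured on the instrumented graph, and the first
schedule matching both budgets at two-decimal rounding — channels
(4, 4, 8, 44), bottleneck 44, giving 243,085 parameters and 332,020,042
MACs — is hard-coded as the default. The MAC convention counts
k²·C_in/groups·C_out·H_out·W_out per convolution and one operation per
output element for every elementwise, pooling, normalization and resampling
stage, the usual multiply-accumulate convention of lightweight-network
profilers.

## Objective, optimization, metrics

The loss is α·Dice + β·BCE with defaults α = 0.7, β = 0.3 and stabilizer
ε = 1e-6 in the Dice denominator and the probability clamp (the BCE term
uses the standard (1−g)·log(1−p); the alternative sweep grid is (1,0),
(0,1), (0.3,0.7), (0.5,0.5), (0.7,0.3)). Optimization is Adam (the
optimizer itself is unspecified upstream; Adam is the field default) at
lr 1e-4, batch 8, 200 epochs, with the learning rate halved after a
10-epoch training-loss plateau and model selection by best monitored DSC.

Metrics come from per-image confusion counts; DSC = 2·IoU/(1+IoU) holds
identically and is asserted per image. Both-empty masks score 1 on all
ratio metrics (perfect agreement; the degenerate case is undefined
upstream). The boundary metric is the symmetric *average* Hausdorff
distance over foreground pixels, computed with Euclidean distance
transforms and verified against an O(n²) all-pairs oracle; it is undefined
(nan, with a warning) when either foreground is empty. Aggregation is the
unweighted per-image mean ± standard deviation.

## Data pipeline

The 7:2:1 split protocol is implemented as test = round(N/10),
val = round(2N/10) (capped to keep training non-empty), train = remainder,
assigned by a seeded shuffle; this reproduces the published test-partition
sizes 215/128/67 for totals 2150/1279/670. (The published train/val counts
for two of the datasets deviate slightly from an exact 7:2:1 and are not
reproduced.) Masks from 8-bit files binarize at 127; predictions threshold
at 0.5 with ties mapping to foreground. Augmentation applies one geometric
transform to image and mask (bilinear vs nearest resampling; reflected
borders for images, zero fill for masks, so no lesion pixels are fabricated
at borders) and adds body-hair noise as quadratic Bézier polylines 1–3 px
thick, darkened toward a sampled intensity — a fully parameterized stand-in
for an upstream augmentation that has no published generative description.
Hair strokes composit onto the image only; mask equality is asserted
exactly.

## Synthetic fixtures

The generator emulates the two task regimes at a qualitative level: a
single large irregular lesion (star-convex polygon with radial harmonics
r(θ) = r₀(1 + Σ aₖ sin(kθ+φₖ)), skin-tone textured background, darker
textured fill, blur, pixel noise, optional hair strokes) and many small
bright nuclei (ellipses placed by rejection sampling under a minimum
separation, on a dark noisy field). Defaults: 64×64 images, mean lesion
radius 0.28 of the image side (foreground fraction ≈ 0.25), 5–15 nuclei of
radius 3–7 px. Every sample is a pure function of (seed, index), so
datasets regenerate byte-identically. The fixtures do **not** model the
intensity statistics, scale variation, occlusions or annotation noise of
dermoscopic/microscopy data, so passing tests establish implementation
correctness and trainability, not clinical segmentation quality; the
published benchmark scores require the real datasets and GPU-scale training
and are out of scope here.

## Problem sizes used by the test suite

The oracle-equivalence suites run ≥20 random instances per block at widths
2–16 and 4–5 px tiles (tolerance 1e-5, float32 forward vs float64 straight
line). The learning smoke test overfits 16 synthetic lesions at 64×64 in
full batch with lr 3e-3 (one optimization step per epoch; the higher rate
compensates for the 300-step budget), requiring DSC ≥ 0.90 within 300
epochs for a majority of three seeds — the default configuration typically
reaches it in 25–60 epochs. The sweep-machinery check trains the default
network for 2 epochs on six 32×32 images per (α, β) row and verifies the
recorded combined loss equals α·dice + β·bce computed by independent
plain-numpy formulas.

## Known limitations

- Stride-1 odd kernels only (downsampling is pooling); no dilation,
  transposed convolution or mixed precision.
- CPU-only numpy execution: fine at fixture scale, not suited to training
  at 256×256 over thousands of images.
- Inference-time benchmarking is hardware-dependent and deliberately
  omitted; the compute proxy is the MAC count.
- `channel_shuffle` is a fixed permutation ("randomly shuffled" upstream is
  read as the standard deterministic interleave the pseudo-code line
  implements).
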