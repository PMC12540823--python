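# Methods

`mambaseg` implements a lightweight 2D encoder–decoder network for binary
lesion segmentation of multi-modal brain MR volumes, together with the
preprocessing, losses, metrics and synthetic data needed to exercise it end
to end on CPU.

## Model

**Encoder.** A stride-2 stem convolution followed by four MBConv stages and
a bridge. Each MBConv block is an inverted bottleneck: 1×1 expansion (ratio
6), depthwise 3×3, 1×1 projection, batch norm after each convolution, SiLU
activations, residual connection when stride is 1 and channel count is
unchanged. Squeeze–excitation is available (`use_se`) but off by default.
Stage widths are (32, 48, 80, 112) with a 192-channel bridge, giving maps at
strides 2/4/8/16/32 for a 224×224×3 input:
112²×32, 56²×48, 28²×80, 14²×112, 7²×192.

**VSS blocks.** Two visual state-space blocks follow every encoder stage,
the bridge, and every decoder stage. A block is: channel layer-norm → four
directional scan branches (row-major forward/reverse, column-major
forward/reverse), each with its own 1×1 expansion to 2C, depthwise 3×3,
SiLU, and a diagonal state-space scan of state size N = 16 → average of the
four outputs → multiplicative SiLU gate computed from the normalized input
→ 1×1 projection back to C → residual add. The scan is the discrete linear
recurrence H(t) = A H(t−1) + B X(t), Y(t) = C H(t) + D X(t) per channel. The
discrete transition is parameterized as A = exp(−exp(A_log)·Δ) with a
learnable softplus step Δ, so |A| < 1 holds structurally and arbitrarily
long scans cannot overflow. The default keeps A, B, C time-invariant, which
is exactly the constant-matrix recurrence above; `selective=True` switches
to input-dependent Δ, B, C (Mamba convention, extra per-position
projections). Scan kernels (forward and adjoint) are numba-compiled.

**Patch merging / expansion.** Merging concatenates each non-overlapping
2×2 neighborhood — order F(x,y), F(x+1,y), F(x,y+1), F(x+1,y+1) with
(x, y) = (column, row) — to 4C channels and linearly projects to 2C
(Swin-style), halving the resolution: 112²×32 → 56²×64, 28²×128 → 14²×256.
Expansion inverts the shapes: a linear map to 2C followed by rearrangement
of each position into a 2×2 block gives (2H, 2W, C/2); it is the decoder's
upsampler and also produces the final 112→224 step before the 1×1 softmax
head.

**Attention bridges.** In the bottleneck and all decoder stages, the VSS
output is fused (elementwise sum by default; concat+1×1 optional) with a
spatial gate (per-pixel mean and max channel descriptors → 7×7 convolution
→ sigmoid; a `literal` mode applies the 7×7 directly to the features) and a
channel gate (global average pooling → C→C/r→C bottleneck, r = 8, ReLU then
sigmoid). Both gates lie in (0,1), so the operators only attenuate.

**Decoder.** Each stage patch-expands the deeper map, concatenates the
VSS-refined encoder skip (skip first, upsampled second), fuses with two 3×3
conv+BN+SiLU layers to the mirrored stage width, then applies VSS ×2 and
the attention bridge.

**Depth and the parameter budget.** The published stage table fixes every
width, so depth is the only dial left for the published ~8.7 M trainable
parameter count. With expansion 6, stage repeats (3, 4, 6, 9) and 8 bridge
blocks the assembled default counts 8.77 M parameters (+0.8 %). Repeats are
config-exposed.

**Initialization.** He-normal convolutions; residual branches start at zero
(VSS output projections and the projection-norm gain of residual MBConv
blocks), so the deep stack behaves like a shallow network early in
training; the 2-class head bias starts at the prior log-odds of the
expected lesion fraction (default 0.05), which removes the large initial
all-background gradient typical of imbalanced segmentation; the narrow
channel-attention bottleneck gets a small positive bias so its ReLU units
start active.

## Losses

Active-contour loss: λ_length·mean(|∇φ|) + λ_region·mean((φ−g)²) with |∇φ|
the L1 norm of forward differences (replicated border). Integrals are pixel
means, not sums, so the defaults λ = (1, 1) are resolution-independent.
Focal loss: mean(−α(1−p_t)^γ log p_t), p_t the probability of the true
class, φ clamped at ε = 1e−7; defaults α = 0.75, γ = 2 (γ is the standard
focal setting; it is not pinned by the ablations we mirror). Hybrid
objective: L_AC + β·L_Focal with β = 0.3. Batch reduction is the mean of
per-slice losses. φ is the softmax foreground-channel probability.

## Metrics

Exact confusion counts give recall, precision, F1 and Dice (F1 ≡ Dice for
binary masks — asserted); mIoU averages per-class IoU t_p/(t_p+f_p+f_n)
over classes present in either map. Surface metrics operate on boundary
pixels (foreground with a background 4-neighbor; the image border counts as
background) scaled to mm: directed average surface distance, their mean
(ASSD) and the plain 100th-percentile Hausdorff distance, via KD-trees.
Conventions: both masks empty → overlap metrics 1 and distances 0; exactly
one empty → overlap 0, distances +inf and a warning flag. Default spacing
is 1 mm isotropic.

## Training

AdamW (decoupled weight decay 1e−5), initial learning rate 1e−4, cosine
annealing to 1e−6 over 100 epochs, batch size 8, early stopping on the
validation hybrid loss with patience 10, validation every epoch,
best-validation weights retained. Augmentation (train split only): rotation
uniform in ±15°, horizontal/vertical flips with probability 0.5 each
applied jointly to image and mask, multiplicative contrast gain in
[0.9, 1.1] on the image with clipping to [0,1]. Optional global
gradient-norm clipping (default ceiling 1.0) and a short linear warmup.

The `tiny` preset (quarter widths 8/12/20/28, bridge 48, single repeats,
expansion 2, state size 8, input 64²) exists for CPU-scale runs; it pairs
with a quick-run recipe (lr 1e−2 with 2 warmup epochs, cosine over 60
epochs, clipping at 1.0). A few hundred optimizer steps cannot move weights
meaningfully at the full-scale 1e−4 rate, and small networks tolerate the
larger step; the default recipe is unchanged.

## Preprocessing

Per-volume, per-modality min–max normalization to [0,1] (a constant volume
maps to zeros, range guarded by ε = 1e−8); modalities concatenated along a
trailing channel axis in input order; axial slicing with an optional
lesion-only filter (training uses only lesion-bearing slices); bilinear
image / nearest-neighbor mask resizing. Arrays are (row, column), 0-based;
the slice index is the third axis. Input size is configurable (the
architecture accepts any multiple of 32; the default stage table is stated
at 224).

## Synthetic data

The generator emulates the statistics the pipeline must survive, not
anatomy: per-modality raw intensity ranges far outside [0,1] (forcing real
normalization), one smooth low-frequency background field shared by all
modalities (smoothing scale 8 voxels, amplitude 0.12 of the range) plus
i.i.d. Gaussian noise (σ = 0.03), and axis-aligned ellipsoidal lesions
(1–3 per volume, in-plane radii 3–7 voxels, axial radius scaled by the
spacing ratio) with a smooth radial intensity falloff √(1−r²) and
modality-dependent contrast — hypointense on the T1-like channel (−0.12),
hyperintense on T2/DWI-like channels (+0.25/+0.40). Default volumes are
64×64×24 at (1, 1, 2.5) mm with 3 modalities. Lesion centers keep the
outermost axial slices lesion-free so the slice filter is always
exercised; lesion voxels stay well under 10 % of the volume. What this
does not model: anatomy, bias fields, partial-volume effects, scanner
variation — passing tests show the pipeline and optimization work, not
clinical performance. Because lesion contrast fades to zero at the
ellipsoid rim by construction, the label boundary is genuinely ambiguous
from intensity alone; synthetic Dice around 0.9 is the practical ceiling
for short runs.

## Numerical choices and conventions

float32 throughout the network; scans compiled with numba; |∇φ| uses the
exact sign subgradient (0 at 0); probability clamps at 1e−7; batch-norm
eval mode uses running statistics (momentum 0.1); max-gate gradients route
to the first argmax. Patch merging rejects odd spatial sizes rather than
padding; the encoder rejects inputs not divisible by 32 before any
computation. Checkpoints embed the network config, seeds and library
versions.

## Known limitations

2D slice-wise only (no volumetric context across slices); binary
lesion-vs-background (multi-region labels out of scope); no pretrained
weights; plain Hausdorff (no 95th percentile); the tiny-preset learning
property is demonstrated on synthetic data only.
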