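# Methods

## Problem setting

Retinal fundus photographs degrade through motion blur, media opacity
("haze", e.g. from cataract), and insufficient illumination. Given a
degraded low-quality (LQ) photograph, the package restores a
high-quality (HQ) estimate with a convolutional encoder–decoder
trained on aligned LQ/HQ pairs. Because clinical pairs are private,
the package also ships a procedural phantom generator and parametric
degradation models, so the entire pipeline is trainable and testable
on synthetic data with known ground truth.

## Degradation models

All images are RGB with intensities in [0, 1]; every operator clips
its output back to that interval.

- **Linear interpolation** between an aligned pair,
  `L_new = (H − L)·λ + L`, λ ∈ [0, 1], synthesizing intermediate
  quality levels (λ defaults for augmentation: 0.2, 0.4, 0.6, 0.8).
- **Gaussian blur**: 2-D convolution with a normalized k×k Gaussian
  kernel (default 5×5, σ = 1.0). σ is not fixed by the protocol the
  defaults mimic; 1.0 gives visible blur at 5×5 support. Boundaries
  are mirror-reflected so the field-of-view rim is not darkened.
- **Haze** via the atmospheric scattering model
  `L(x) = H(x)·t(x) + (1 − t(x))·A`, with transmission
  `t(x) = exp(−β·d(x))`, extinction coefficient β (per unit depth),
  RGB airlight A, and a crafted depth map d. Three depth families are
  provided: `constant` (homogeneous transmission), `axial_ramp`
  (one-sided haze along a seeded random orientation), and `radial`
  (`d = peak·(ρ/R)²`, haze concentrated toward the rim/corners). Both
  the homogeneous and spatially varying cases are supported because
  both appear in practice; samplers default to β ∈ [0.5, 2.0],
  per-channel A ∈ [0.7, 1.0], family uniform.
- **Low illumination** by gamma darkening `L = H^(1/γ)`, 0 < γ ≤ 1
  (sampler default γ ∈ [0.4, 0.9]: visible but invertible darkening).
- **Rotation** by exact 90°/180°/270° index permutation (augmentation
  only; it would break LQ/HQ pixel alignment if applied one-sided).

A note on a formula as sometimes printed for the blur sum,
`H(x−i, y−i)`: it is treated as a typo for the standard 2-D
convolution `H(x−i, y−j)`.

## Network

The building block (`AttOpBlk`) applies five parallel operations to
its input feature map X — 1×1, 3×3, 5×5, 7×7 convolutions and a 3×3
max pool — all preserving spatial size and channel count. A channel
attention head computes the per-channel spatial average C of X, maps
it through a 3-layer MLP (hidden width = channel count), applies a
final ReLU, and softmax-normalizes the five logits into weights
Ā (Σ Ā = 1, Ā ≥ 0). The output is
`S = F_c(Σ_i Ā_i·Y_i ⊕ X)` where Y_i are the branch outputs, ⊕ is
channel concatenation and F_c a 1×1 convolution. The concatenated X
acts as a residual path: even with the fused half zeroed, gradients
reach the block input. Design notes:

- The ReLU precedes the softmax, as specified; when all
  pre-activations are nonpositive the logits collapse to zero and the
  weights become uniform (1/5 each). A single-matrix attention head
  (`attention_layers=1`) is available as a config flag.
- The max-pool branch uses stride 1 and padding 1 (pad value −∞) so
  all five branches are shape-compatible for the weighted sum; pool
  stride is otherwise unconstrained by the architecture description.
- Convolution branches use reflection padding (replication on
  degenerate 1-pixel axes); biases are enabled everywhere.

The full model: a 3×3 stem convolution to `base_channels`, then four
encoder levels, each an `AttOpBlk` followed by a stride-2 3×3
convolution (spatial ÷2, channels ×2). At full scale
(base 64) a 320×320×3 input reaches a 20×20×1024 latent. The decoder
mirrors with 3×3 transposed convolutions (stride 2, output padding 1:
spatial ×2, channels ÷2); each level concatenates the matching
encoder output (U-Net skip), reduces with a 1×1 merge convolution,
and applies an `AttOpBlk`. The merge keeps decoder block widths equal
to encoder widths, which keeps the per-level cost symmetric; the
exact interior composition of the blocks is this package's contract,
as only the downsample/upsample layers are externally constrained. A
final 3×3 convolution maps to 3 channels, so output shape equals
input shape. Channel schedule 3→64→128→256→512→1024 at full scale:
the only doubling schedule reaching 2^10 from a conventional base of
64 over four levels.

Weights are He-initialized from a per-model seeded generator;
building and forward passes are bit-deterministic per seed. A
`make_near_identity` helper rewires any model into an exact identity
map (stem embeds RGB, fusions select the residual half, last merge
selects the skip, head reads the embedding back), useful as an
untrained baseline and for verifying the skip topology.

The network and its training loop are implemented directly over NumPy
with a small reverse-mode autodiff engine (`fundusenhance.nn.autograd`):
convolutions as single-GEMM im2col products whose backward pass
recomputes the column matrix instead of caching it (a full-scale
320×320 forward stays under ~2 GB), plus the handful of other ops the
model needs. All ops are verified against finite differences in the
test suite.

## Training

Objective: `(1/N_batch)·Σ_i ‖ŷ_i − y_i‖₁ + (λ/2)·‖W‖²` with λ = 0.1.
The per-image L1 norm is the *sum* of absolute pixel differences by
default; a per-pixel-mean variant (`pixel_mean=True`) exists because
at reduced patch sizes the summed loss is of order 10⁴ and the
full-scale learning rate diverges. Optimizer: SGD with momentum 0.9;
learning rate `lr(e) = lr₀·0.9^(e/100)` ("decay 0.9" is read as
learning-rate decay with a 100-epoch period; both are configurable).

Presets:

| parameter | paper_full | desk_small |
|---|---|---|
| patch size | 320 | 64 |
| base channels | 64 | 8 |
| batch size | 16 | 8 |
| initial lr | 0.01 | 0.005 |
| epochs × iters | 1000 × ~300 | 10 × 20 (200 iterations) |
| L1 reduction | sum | pixel mean |
| weight decay λ | 0.1 | 1e-4 |
| grad-norm clip | — | 10.0 |

The desk_small deviations are scale-driven: with mean-mode L1 the
loss is ~10⁴× smaller, so λ shrinks proportionally, and 0.01 is
unstable at this width/batch — 0.005 is the largest rate that trains
stably. Global gradient-norm clipping (threshold 10, roughly an
order of magnitude above steady-state norms) absorbs the He-init
transient, whose gradient norms can spike by 10²–10³ in the first
iterations at unlucky seeds. Training patches follow the 5 macula / 10 crossing / 5 random
protocol at the preset's patch size; "around the macula" is
operationalized as uniform center jitter within patch_size/10 pixels
(the protocol does not define "around"). Crossings are sampled
without replacement while enough remain. No early stopping: fixed
iteration counts.

## Inference

Whole images are covered with a non-overlapping grid of
patch-size tiles, reflection-padded up to the next multiple and
cropped back after reassembly (`untile(tile(x)) == x` exactly, for
any size). When the input carries a field-of-view mask, the output's
exterior is reset to black: the aperture region is black by
construction, carries no retinal signal, and lies outside the
training patch distribution, so the network's extrapolation there is
meaningless and would otherwise dominate whole-image error metrics.

## Synthetic phantoms

`generate_fundus` renders a fundus-like image: circular field of view
(radius 0.48×side), orange-red background (base RGB ≈
(0.72, 0.34, 0.12)) with quadratic vignetting and low-frequency
illumination waves, a bright optic disc (Gaussian blob displaced
~0.55·R horizontally), a darker macula near the center, and a dark
vessel tree rooted at the disc. Vessels are grown by recursive binary
branching with random-walk jitter and per-branch curvature,
decreasing width toward the periphery. Two trees are grown
independently and overlaid, so transversal crossings exist by
construction; recorded crossing coordinates are snapped to skeleton
pixels with ≥3 skeleton neighbors, deduplicated within 5 px, and
extra curved branches are grown until at least 10 crossings exist.
The default side is 640 px (a desk-scale stand-in for multi-megapixel
acquisitions; anything ≥256 is accepted). Everything flows from one
explicit seed; repeated calls are bit-identical.

What the phantoms do *not* emulate: disease lesions (drusen, holes,
hemorrhages), photoreceptor texture, camera vignetting profiles or
sensor noise statistics of real devices, eyelash/tear artifacts, and
misregistration between the pair (synthetic pairs are pixel-aligned
by construction, real pairs require registration upstream). Passing
tests therefore demonstrate that the pipeline restores the modeled
degradations on aligned pairs — not clinical-grade enhancement.

## Metrics

PSNR (`10·log₁₀(range²/MSE)`, capped at 100 dB for identical images),
SSIM (canonical constants: 11×11 Gaussian window σ = 1.5, K1 = 0.01,
K2 = 0.03, data range 1, per-channel mean), and the linear index of
fuzziness `r = (2/MN)·Σ min(μ, 1−μ)` on luma (0.299, 0.587, 0.114)
memberships — lower r means a crisper image. r is computed on
grayscale over the full frame by default; field-of-view-masked
evaluation is opt-in. Aggregates are mean ± sample standard
deviation.

A direction caveat worth knowing: on images whose luma sits below
0.5 (fundus backgrounds), gamma darkening *lowers* r, so for
gamma-degraded synthetic pairs r(LQ) < r(HQ) and a faithful
restoration *raises* r back toward the HQ value. Haze toward a
mid-gray airlight has the opposite sign. r comparisons across
enhancement methods are therefore only meaningful per degradation
regime.

## Numerical choices

- Network math in float32 (configurable); degradation and metric math
  in float64.
- All degradations clip to [0, 1]; enhancement output clipped before
  the fov reset.
- Max-pool backward routes gradient to the first arg-max on ties.
- Reflection padding uses the no-edge-repeat convention everywhere
  (NumPy "reflect" / scipy "mirror"), degenerating to replication on
  single-pixel axes.
- PSNR of identical images returns the 100 dB cap instead of ∞.
- Patch origins are clipped to image bounds, so patches near the rim
  shift inward rather than shrink.

## Limitations

- Training at the full-scale preset (74.5 M parameters, 1000 epochs)
  is far outside CPU budgets; the desk_small preset demonstrates the
  mechanism, not clinical performance.
- No image registration: real LQ/HQ pairs must be aligned upstream.
- The fuzziness index direction depends on the degradation regime
  (see above).
- Single-image inference is deterministic but not batched across
  images; throughput is secondary to reproducibility here.
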