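# Methods

## Acquisition model

Images are single-channel magnitudes in [0, 1]. The forward model is an
orthonormal (unitary) 2-D DFT with the DC component shifted to the grid
center; the 1/√N scaling on each direction makes Parseval's identity hold to
machine precision, so loss magnitudes — and therefore the printed loss
weights — transfer unchanged between the image and frequency domains and
across image sizes. Retrospective undersampling multiplies the spectrum by a
binary mask and zero-fills; the magnitude of the inverse transform is the
degraded network input.

### Sampling masks

Masks are 2-D point-wise (each k-space point an independent candidate),
which maximizes incoherence under a Gaussian variable-density profile. A
centered square whose area is the nearest achievable to 4% of the grid is
always fully sampled; the remaining points are drawn **without replacement**
with probability proportional to `exp(−d²/2σ²)`, `σ = sigma_scale ·
min(H, W)`. Drawing without replacement (rather than Bernoulli thresholding)
makes the realized rate equal `round(rate·H·W)` exactly and keeps test
cardinalities deterministic. Defaults: `center_fraction = 0.04`,
`sigma_scale = 0.25` (no principled value exists for the width; 0.25·min(H,W)
concentrates roughly two thirds of the free samples inside the inner half of
k-space, a typical variable-density profile). A square center was chosen
over a circle because its cardinality is exactly controllable; the geometry
is isolated behind `center_slices` should a circular variant be wanted.

## Phantoms

The synthetic data generator renders piecewise-constant ellipse phantoms: a
bright thin "skull" rim, nested random tissue ellipses at configurable
intensity levels, a bright compact central blob, optional additive Gaussian
noise, clipped to [0, 1]. This reproduces the features the networks rely on
— piecewise-smooth tissue regions, sharp edges, a high-energy k-space center
— and is deterministic per seed. It does **not** emulate tissue relaxometry,
coil sensitivity profiles, phase, or anatomical variability, so passing
tests demonstrate that the pipeline removes retrospective undersampling
artifacts from piecewise-smooth magnitude images; they do not certify
performance on scanner data.

Augmentation applies exactly one of four transforms per draw, each with
probability 1/4: vertical flip, horizontal mirror, 90° rotation, or integer
translation uniform in ±10% of each dimension with zero padding (the bound
keeps the head inside the field of view). Augmentation is applied online,
per sample per epoch, never materialized. Datasets are split 70/10/20 by a
seeded shuffle with the remainder assigned to training.

## Networks

All layers run on the package's own float64 reverse-mode autodiff engine
(`autodiff.py`, `nn.py`); gradients of every operator are verified against
central finite differences in the test suite.

**Generator** — U-net with `depth` encoder levels (default 4, channels
doubling from `base_channels` = 32). Each level applies a channel-lifting
3×3 convolution (after 2×2 max-pool downsampling for levels > 1), then three
dilated residual blocks with dilation rates (1, 2, 3), then channel
attention. A DR block is conv3×3 → BN → ReLU → conv3×3(dilation r, padding
r) → BN → +identity → ReLU; dilating the second convolution enlarges the
receptive field (the (1,2,3) stack spans 19×19) at an unchanged parameter
count. The decoder mirrors the encoder with corner-aligned bilinear
upsampling and skip-connection concatenation. A multi-scale fusion head
projects every decoder resolution to a common width with 1×1 convolutions,
bilinearly upsamples to full resolution, sums, and fuses with one 3×3
convolution. The 1×1 output head is **zero-initialized** and the network
predicts a residual added to its input, so the untrained generator is
exactly the identity — this stabilizes small-scale adversarial training and
makes the no-training baseline well defined. DR blocks live in the encoder
only; decoder-side DR blocks were considered and rejected to keep the
parameter budget in the path that builds the representation.

**Channel attention** — per-channel global max- and average-pooled
statistics pass through a two-layer bottleneck MLP whose weights are shared
across channels (hidden width `max(1, C // reduction)`, reduction 8); the
two paths are summed (concatenation of the two statistics is available via
config) and a logistic squashing yields per-channel weights in (0, 1).
Sharing the transform across channels makes the attention permutation-
equivariant — channels with identical content provably receive identical
weights — at the cost of explicit cross-channel mixing; the global residual
path and the convolutions provide channel interaction elsewhere.

**Discriminator** — `n_layers` (default 4) stride-2 3×3 convolutions, batch
normalization after every convolution except the first (standard for this
family), LeakyReLU (slope 0.2), then global average pooling, an affine map
and a logistic output. Downsampling is by stride only; the layer graph
contains no pooling operator, which the tests assert structurally.

## Losses

All "½‖·‖²" terms are ½ × *mean* (not sum) squared error so magnitudes are
resolution-independent. Under the unitary FFT the frequency-domain term is
mathematically identical to the image-domain term for real images (Parseval)
— asserted as a test — so the effective pixel-domain weight is α + β; the
term is still computed honestly from the spectra and kept separate because
the two terms diverge under any non-unitary convention or complex-valued
extension. The perceptual term uses an injectable extractor; the default is
a fixed, seeded, three-layer random convolution stack (frozen, deterministic,
differentiable with respect to its input). Random convolutional features
preserve local texture discrepancies well enough to regularize
over-smoothing at this scale; swapping in pretrained VGG16 features amounts
to passing a different callable. Probabilities are clamped to
[10⁻⁷, 1−10⁻⁷] before logarithms. The adversarial term carries an optional
weight `gamma` (default 1, i.e. the standard combination); `gamma=0` turns
training into supervised regression, which the tests use as a descent sanity
check.

## Training

1:1 per-batch alternation: one discriminator ADAM step on real images versus
detached reconstructions, then one generator step on the combined loss
(`disc_steps` exposes k:1). ADAM β₁=0.9, β₂=0.999, lr₀=10⁻⁴, halved every 10
epochs; patience-20 early stopping on validation MSE with best-checkpoint
retention. Each training sample receives a fresh mask every epoch (the model
sees maximal mask incoherence), while validation images keep one fixed mask
each, derived from the global seed, so validation metrics are reproducible
across epochs, runs and ablation variants (the ablation table records a mask
hash to prove it). Non-finite losses abort with a diagnostic dump. Given a
seed, training is bit-reproducible under single-threaded execution.

## Metrics

MSE is the plain mean squared difference (no ½). PSNR = 10·log₁₀(1/MSE) for
data range 1, capped at 100 dB for numerically perfect reconstructions so
reports serialize. SSIM uses the standard 11×11 Gaussian window, σ=1.5,
K₁=0.01, K₂=0.03 (via scikit-image). Per-pixel squared-error maps export as
8-bit PNG heatmaps for inspection only.

## Problem sizes used by the test suite

The tiny-scale end-to-end experiment trains on 120 phantoms of 64×64 (noise
sd 0.01) with a depth-3 / base-8 generator, 3-layer / base-8 discriminator,
batch 4, 20% sampling, 300 alternating steps — after which held-out
reconstruction PSNR exceeds the zero-filled baseline by ≥1 dB. Unit and
property tests use 32×32 images and depth-2 networks. These sizes are the
package's reference small-scale study; all of them are configurable, and
the defaults (depth 4, base 32, batch 16, 50 epochs, 256×256 slices) match
a realistic full-scale run.

## Known limitations

- Magnitude-only, single-coil, Cartesian point-wise sampling; no
  non-Cartesian trajectories, parallel imaging, or complex-valued inputs.
- The numpy engine is single-threaded and float64: correct and inspectable,
  but orders of magnitude slower than GPU frameworks; full-scale training
  on real MPRAGE volumes is out of its intended scope.
- Phantom realism as discussed above; NIfTI ingestion exists for real
  slices but no shipped test depends on external data.
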