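# Methods

This note records the scientific and numerical conventions behind
`fundusgan`: what each component computes, which choices are fixed by
definition, and which are configurable design decisions.

## Overview

The package synthesizes retinal fundus images with a conditional
Wasserstein GAN with gradient penalty (WGAN-GP). The generator
`G(y, D(x), z)` receives a binary vessel-segmentation mask `y`, a
two-channel lesion descriptor `D(x)` extracted from a reference image,
and a noise vector `z`; the critic `D_γ(x, y)` scores image/mask pairs.
Training alternates `n_critic` critic updates with one generator update.

Losses:

- **Wasserstein gap** `L_W = mean D_γ(x, y) − mean D_γ(x̂, y)`; the critic
  maximizes it, subject to
- **gradient penalty** `λ_gp · mean (‖∇_{x̃} D_γ(x̃, y)‖₂ − 1)²` at
  per-sample uniform interpolates `x̃ = u·x + (1−u)·x̂`, `u ~ U(0,1)`
  (two-sided penalty, `λ_gp = 10`);
- **generator loss** `L_G = −mean D_γ(x̂, y) + w_p·L_percept + w_s·L_severity`
  with `w_p = w_s = 1` by default;
- **severity loss** `L_severity = mean |DR(x) − DR(x̂)|`, where `DR(·)`
  is a scalar severity regressor (absolute difference, because the
  severity scale is ordinal and scalar);
- **perceptual loss** `L_percept = mean (F^λ(x) − F^λ(x̂))²`, the squared
  feature distance at stage `λ` averaged over all feature elements
  (default `λ = stage2`).

## Stand-in networks

A single small convolutional network (the *grader*) plays three roles
that full-scale systems delegate to external models: severity scorer
`DR(·)`, perceptual feature extractor `F^λ`, and FID embedder. Any
user-supplied network with the same interface can be plugged into each
role.

The grader has a full-resolution 3×3 stem (the spatial context is what
separates small round lesions from thin vessels of nearly the same
color) followed by three stride-2 stages. It is trained on per-pixel
lesion-density targets: segmentation heads predict the lesion-mask union
at full resolution and fine/coarse densities at stages 1–2, with
positive pixels upweighted 20×. The scalar grade head is then solved in
closed form (ridge regression) on the five pooled rectified
segmentation densities. Restricting the grade head to lesion-density
features keeps the grade's input gradient concentrated on lesion pixels,
which the saliency-based lesion extraction relies on. Held-out quality
is reported as within-one-grade accuracy.

## Lesion extraction

`D(x)` is computed from the trained grader by backpropagation:

1. **saliency** = channel-summed absolute input gradient of the scalar
   grade output (the simplest operator consistent with gradient
   backpropagation, exactly testable against finite differences);
2. Gaussian smoothing at two scales (σ_fine = 1 px, σ_coarse = 4 px;
   kernels truncated at 4σ, renormalized, reflect padding);
3. binarization of each smoothed map at its own empirical (1−q) quantile
   (default q = 0.02) computed over field-of-view pixels only; ties at
   the threshold are included. Quantile thresholds are invariant to the
   saliency magnitude, which a fixed threshold is not.

The two binary maps ("fine" and "coarse") share the image resolution and
differ in smoothing scale.

## Resampling kernels

Preprocessing and the generator's decoder upsampling share one
`ResampleSpec` (kernel + antialias flag), so a named kernel
configuration acts end to end. Separable resampling with half-pixel
centers (`s = (d + 0.5)·scale − 0.5`), clamp-to-edge, per-row weight
renormalization, output clipped to [0,1]. Kernels: nearest (half-up
toward the larger index), bilinear (tent), bicubic (Keys, a = −0.5),
mitchell (Mitchell–Netravali, B = C = 1/3), lanczos5. `antialias`
stretches the kernel by 1/scale when downscaling only. Identity-size
resizes are returned unchanged (short-circuit) for every kernel.

## Metrics

- **FID** `= ‖μ_r − μ_g‖² + Tr(Σ_r + Σ_g − 2(Σ_r Σ_g)^{1/2})` over
  Gaussian fits of embedded feature rows (covariance denominator n−1).
  The matrix square root uses the eigendecomposition of the symmetrized
  product `√Σ_r Σ_g √Σ_r`; eigenvalues in [−1e−10, 0) are numerical
  residue and are clipped, anything more negative raises. FID values
  are only comparable within one embedder; reports record which was
  used. The default embedder is the grader's stage-λ features averaged
  over space.
- **MSE** over all pixels/channels of [0,1] floats (before any 8-bit
  quantization).
- **SSIM** with C1 = (0.01 L)², C2 = (0.03 L)², L = 1. `windowed` mode
  (default) uses an 11×11 Gaussian window (σ = 1.5, reflect padding)
  and averages the SSIM map; `global` mode evaluates the formula once
  with whole-image moments (useful for closed-form checks). RGB inputs
  are reduced to grayscale by the channel mean.
- **evaluate** pairs each real sample with a generated sample under the
  same conditioning; MSE/SSIM are paired means, FID compares the pooled
  sets, and repeats vary only the noise seed, reported as mean ± sd
  (ddof 1).

## Synthetic data

The procedural generator draws, per sample: a circular field of view
(radius 0.48·side), a bright optic disc ellipse, a vessel tree grown
from the disc by branching random walks (rasterized into the paired
mask), a grade g uniform on {0..4}, a lesion count uniform on
[4g, 4g+3], dark/bright elliptical lesions placed in the field of view
(blob area ≤ 9 px → fine mask, else coarse), and additive Gaussian
noise. The grading rule makes grade a simple function of lesion count,
so the labels are learnable by construction; it is a test convenience,
not a claim about clinical grading. Samples are bitwise reproducible
from (config, seed, index).

## Training and reproducibility

Adam (lr 1e−4, betas (0.0, 0.9)), `n_critic = 5`, batch 16. Lesion
descriptors `D(x)`, severity scores `DR(x)` and perceptual features
`F(x)` of real images are pure functions of the frozen grader, so they
are computed once per image before the loop and cached. Every random
draw comes from one seeded PCG64 stream whose exact state is serialized
into checkpoints: a resumed run replays the identical remainder of an
unbroken run, and identical (config, seed) reruns are bitwise identical.
Training arithmetic defaults to float32 for speed; float64 is available
(`TrainConfig.dtype`) and is used by all exactness tests of the loss
definitions.

### Critic initialization

Critic weights are initialized 1.6× above He scale (`init_gain`). At He
scale, a random critic's input-gradient norm at interpolates already
sits near 1, so the gradient penalty starts satisfied and the only
subsequent dynamic is the Wasserstein gap slowly pushing the norm away
from 1. Starting above He scale (initial norm ≈ 13 at the default
width) makes the critic visibly non-1-Lipschitz at initialization, and
the penalty then does observable work: the interpolate gradient norm
falls by an order of magnitude toward 1 during training and equilibrates
near `1 + O(gap growth / λ_gp)`.

## Numerical conventions

- Images are H×W×3 float arrays in [0,1]; computation uses NCHW
  internally.
- All autodiff is a self-contained reverse-mode engine over numpy with
  support for double backpropagation (needed because the gradient
  penalty differentiates through the critic's input gradient).
- Gradient norms use `sqrt(Σg² + 1e−24)` to keep the penalty
  differentiable at zero gradient.
- On-disk images are 8-bit PNG; arrays on the 8-bit lattice round-trip
  exactly.
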