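"""Conditional Wasserstein GAN with gradient penalty.

The generator maps a conditioning stack — vessel mask ``y`` (one channel)
plus the fine/coarse lesion descriptor maps (two channels) — and a noise
vector ``z`` to an RGB fundus image in [0,1].  The critic scores an
(image, vessel-mask) pair with an unbounded real value.  Training
minimises, over generator parameters, the negative critic score of the
synthesised image plus weighted perceptual and severity terms, while the
critic maximises the Wasserstein gap subject to a two-sided gradient
penalty at uniform interpolates (the standard WGAN-GP construction,
coefficient 10 by default).

Architecture notes (CPU-scale defaults; widths and the noise size are
configuration):

* generator: 4-stage stride-2 conv encoder over the condition stack;
  noise injected at the bottleneck by linear projection; decoder stages
  upsample with the active resampling spec (``lin2d`` against cached
  resize matrices) followed by convolution, with skip connections from
  the condition encoder; final 1x1 conv + sigmoid;
* critic: 4 stride-2 convolutions over the channel-concatenated
  (image, mask) pair, flattened into a linear score; no output
  nonlinearity.

The critic conditions on (x, y) only — lesion descriptors steer the
generator but are not shown to the critic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._util import to_nchw
from .resample import ResampleSpec, weight_matrix


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: perceptual, severity, and gradient-penalty terms."""

    wp: float = 1.0
    ws: float = 1.0
    lambda_gp: float = 10.0

    def __post_init__(self):
        for name in ("wp", "ws", "lambda_gp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def _leaky(x, slope=0.2):
    return nn.leaky_relu(x, slope)


class GeneratorModel:
    """Encoder-decoder generator G(y, D(x), z) -> image in [0,1]^(HxWx3)."""

    N_COND = 3  # vessel mask + fine/coarse lesion maps

    def __init__(self, side: int = 64, base_width: int = 8, z_dim: int = 128,
                 resample: ResampleSpec = ResampleSpec("bilinear"), init_seed: int = 0):
        if side % 16 != 0:
            raise ValueError("generator side must be divisible by 16")
        self.side = int(side)
        self.base_width = int(base_width)
        self.z_dim = int(z_dim)
        self.resample = resample
        self.init_seed = int(init_seed)
        w = self.base_width
        ws = (w, 2 * w, 4 * w, 4 * w)
        self.widths = ws
        bott = side // 16
        rng = np.random.default_rng(np.random.SeedSequence([self.init_seed, 0x6E2]))
        P: dict[str, nn.Tensor] = {}
        # condition encoder
        chans = [self.N_COND, *ws]
        for i in range(4):
            P[f"enc{i}_w"] = nn.he_conv(rng, chans[i + 1], chans[i], 3)
            P[f"enc{i}_b"] = nn.zeros(1, chans[i + 1], 1, 1)
        # noise projection to the bottleneck feature map
        P["z_w"] = nn.he_linear(rng, ws[3] * bott * bott, self.z_dim)
        P["z_b"] = nn.zeros(1, ws[3] * bott * bott)
        # decoder: upsample (resample spec) + conv over [up, skip]
        dec_in = (ws[3] + ws[2], ws[2] + ws[1], ws[1] + ws[0], ws[0] + self.N_COND)
        dec_out = (ws[2], ws[1], ws[0], w)
        for i in range(4):
            P[f"dec{i}_w"] = nn.he_conv(rng, dec_out[i], dec_in[i], 3)
            P[f"dec{i}_b"] = nn.zeros(1, dec_out[i], 1, 1)
        P["out_w"] = nn.he_conv(rng, 3, w, 1)
        P["out_b"] = nn.zeros(1, 3, 1, 1)
        self.params = P

    def _upsample(self, t: nn.Tensor, out_side: int) -> nn.Tensor:
        in_side = t.shape[2]
        m_r = weight_matrix(in_side, out_side, self.resample.kernel, self.resample.antialias)
        m_c = weight_matrix(t.shape[3], out_side, self.resample.kernel, self.resample.antialias)
        return nn.lin2d(t, m_r, m_c)

    def forward(self, cond: nn.Tensor, z: nn.Tensor) -> nn.Tensor:
        """cond: (N, 3, H, W); z: (N, Z) -> image tensor (N, 3, H, W)."""
        if cond.shape[1] != self.N_COND:
            raise ValueError(f"condition stack must have {self.N_COND} channels, got {cond.shape[1]}")
        if cond.shape[2] != self.side or cond.shape[3] != self.side:
            raise ValueError(f"generator expects side {self.side}, got {cond.shape[2:]} input")
        if z.shape[1] != self.z_dim:
            raise ValueError(f"noise must have {self.z_dim} dims, got {z.shape[1]}")
        P = self.params
        skips = [cond]
        h = cond
        for i in range(4):
            h = _leaky(nn.conv2d(h, P[f"enc{i}_w"], 2, 1) + P[f"enc{i}_b"])
            skips.append(h)
        bott = self.side // 16
        zmap = nn.matmul(z, P["z_w"]) + P["z_b"]
        h = h + nn.reshape(zmap, (z.shape[0], self.widths[3], bott, bott))
        for i in range(4):
            out_side = bott * 2 ** (i + 1)
            up = self._upsample(h, out_side)
            skip = skips[3 - i]
            h = _leaky(nn.conv2d(nn.concat([up, skip], axis=1), P[f"dec{i}_w"], 1, 1) + P[f"dec{i}_b"])
        return nn.sigmoid(nn.conv2d(h, P["out_w"], 1, 0) + P["out_b"])

    def meta(self) -> dict:
        return {
            "side": self.side,
            "base_width": self.base_width,
            "z_dim": self.z_dim,
            "resample_kernel": self.resample.kernel,
            "resample_antialias": self.resample.antialias,
            "init_seed": self.init_seed,
        }

    @classmethod
    def from_meta(cls, meta: dict) -> "GeneratorModel":
        return cls(side=meta["side"], base_width=meta["base_width"], z_dim=meta["z_dim"],
                   resample=ResampleSpec(meta["resample_kernel"], meta["resample_antialias"]),
                   init_seed=meta["init_seed"])


class CriticModel:
    """Wasserstein critic D(x, y): unbounded scalar score per pair.

    Weights are initialised ``init_gain`` times above He scale.  At He
    scale the random critic's input-gradient norm already sits near 1,
    so the gradient penalty starts satisfied and has nothing to
    calibrate; a super-He start makes the critic visibly non-1-Lipschitz
    and lets the penalty pull the norm toward 1 during training.
    """

    def __init__(self, side: int = 64, base_width: int = 8, init_seed: int = 0,
                 init_gain: float = 1.6):
        if side % 16 != 0:
            raise ValueError("critic side must be divisible by 16")
        self.side = int(side)
        self.base_width = int(base_width)
        self.init_seed = int(init_seed)
        self.init_gain = float(init_gain)
        w = self.base_width
        ws = (w, 2 * w, 4 * w, 4 * w)
        self.widths = ws
        rng = np.random.default_rng(np.random.SeedSequence([self.init_seed, 0xC417]))
        P: dict[str, nn.Tensor] = {}
        chans = [4, *ws]  # RGB image + vessel mask
        for i in range(4):
            P[f"conv{i}_w"] = nn.he_conv(rng, chans[i + 1], chans[i], 3)
            P[f"conv{i}_w"].data = P[f"conv{i}_w"].data * self.init_gain
            P[f"conv{i}_b"] = nn.zeros(1, chans[i + 1], 1, 1)
        flat = ws[3] * (side // 16) ** 2
        P["out_w"] = nn.he_linear(rng, 1, flat)
        P["out_w"].data = P["out_w"].data * self.init_gain
        P["out_b"] = nn.zeros(1, 1)
        self.params = P

    def score(self, x: nn.Tensor, y: nn.Tensor) -> nn.Tensor:
        """x: (N,3,H,W) image; y: (N,1,H,W) mask -> (N,) scores."""
        if x.shape[2:] != (self.side, self.side):
            raise ValueError(f"critic expects side {self.side}, got {x.shape[2:]}")
        if y.shape[2:] != x.shape[2:]:
            raise ValueError("image and mask spatial sizes differ")
        P = self.params
        h = nn.concat([x, y], axis=1)
        for i in range(4):
            h = _leaky(nn.conv2d(h, P[f"conv{i}_w"], 2, 1) + P[f"conv{i}_b"])
        h = nn.reshape(h, (h.shape[0], int(np.prod(h.shape[1:]))))
        out = nn.matmul(h, P["out_w"]) + P["out_b"]
        return nn.reshape(out, (out.shape[0],))

    def meta(self) -> dict:
        return {"side": self.side, "base_width": self.base_width,
                "init_seed": self.init_seed, "init_gain": self.init_gain}

    @classmethod
    def from_meta(cls, meta: dict) -> "CriticModel":
        return cls(side=meta["side"], base_width=meta["base_width"],
                   init_seed=meta["init_seed"], init_gain=meta.get("init_gain", 1.6))


# ---------------------------------------------------------------------------
# conditioning helpers
# ---------------------------------------------------------------------------

def condition_stack(vessel_mask: np.ndarray, lesions: np.ndarray) -> np.ndarray:
    """Assemble (N,3,H,W) condition input from masks.

    ``vessel_mask``: (H,W) or (N,H,W); ``lesions``: (2,H,W) or (N,2,H,W)
    fine/coarse descriptor maps.
    """
    vm = np.asarray(vessel_mask, dtype=np.float64)
    le = np.asarray(lesions, dtype=np.float64)
    if vm.ndim == 2:
        vm = vm[None]
    if le.ndim == 3:
        le = le[None]
    if le.shape[1] != 2:
        raise ValueError("lesion descriptor must have 2 channels (fine, coarse)")
    return np.concatenate([vm[:, None], le], axis=1)


# ---------------------------------------------------------------------------
# losses (graph-building forms return Tensors; batch means throughout)
# ---------------------------------------------------------------------------

def wasserstein_gap(critic, x: nn.Tensor, xhat: nn.Tensor, y: nn.Tensor) -> nn.Tensor:
    """Mean critic score of real pairs minus mean score of synthesised pairs."""
    return nn.tmean(critic.score(x, y)) - nn.tmean(critic.score(xhat, y))


def gradient_penalty_term(critic, x: nn.Tensor, xhat: nn.Tensor, y: nn.Tensor,
                          u: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
    """Two-sided gradient penalty at interpolates ``u*x + (1-u)*xhat``.

    ``u`` is one uniform draw per batch element.  Returns (penalty,
    mean gradient norm); both stay on the tape so critic training can
    differentiate through the input-gradient norm.
    """
    if x.shape[0] != xhat.shape[0]:
        raise ValueError("real and synthetic batch sizes differ")
    u = np.asarray(u, dtype=x.data.dtype).reshape(-1, 1, 1, 1)
    x_tilde = nn.Tensor(u * x.data + (1.0 - u) * xhat.data, requires_grad=True)
    score = nn.tsum(critic.score(x_tilde, y))
    g = nn.grad(score, x_tilde)
    sq = nn.tsum(nn.mul(g, g), axis=(1, 2, 3))
    norms = nn.sqrt(sq + 1e-24)
    penalty = nn.tmean(nn.power(norms - 1.0, 2.0))
    return penalty, nn.tmean(norms)


def severity_gap(grader, x: nn.Tensor, xhat: nn.Tensor) -> nn.Tensor:
    """Mean |DR(x) - DR(xhat)| over the batch (scalar-grade convention)."""
    return nn.tmean(nn.absolute(grader.forward(x) - grader.forward(xhat)))


def perceptual_gap(feature_net, layer: str, x: nn.Tensor, xhat: nn.Tensor) -> nn.Tensor:
    """Element-averaged squared feature difference at stage ``layer``."""
    fx = feature_net.features_tensor(x, layer)
    fg = feature_net.features_tensor(xhat, layer)
    return nn.tmean(nn.power(fx - fg, 2.0))


def generator_objective(critic, grader, feature_net, layer: str,
                        x: nn.Tensor, xhat: nn.Tensor, y: nn.Tensor,
                        weights: LossWeights) -> tuple[nn.Tensor, dict]:
    """Generator loss: -E[D(xhat,y)] + wp*Lpercept + ws*Lseverity."""
    adv = nn.neg(nn.tmean(critic.score(xhat, y)))
    percept = perceptual_gap(feature_net, layer, x, xhat)
    severity = severity_gap(grader, x, xhat)
    total = adv + weights.wp * percept + weights.ws * severity
    parts = {
        "adversarial": adv.item(),
        "perceptual": percept.item(),
        "severity": severity.item(),
        "total": total.item(),
    }
    return total, parts


def critic_objective(critic, x: nn.Tensor, xhat: nn.Tensor, y: nn.Tensor,
                     weights: LossWeights, u: np.ndarray) -> tuple[nn.Tensor, dict]:
    """Critic loss: -(Wasserstein gap) + lambda_gp * gradient penalty.

    The real and synthetic batches go through the critic as one
    concatenated batch (arithmetically identical to two passes, since
    convolutions act per batch element); the interpolates get their own
    pass because the penalty is differentiated through it twice.
    """
    if x.shape[0] != xhat.shape[0]:
        raise ValueError("real and synthetic batch sizes differ")
    n = x.shape[0]
    scores = critic.score(nn.concat([x, xhat], axis=0), nn.concat([y, y], axis=0))
    gap = nn.tmean(nn.narrow(scores, 0, 0, n)) - nn.tmean(nn.narrow(scores, 0, n, n))
    penalty, grad_norm = gradient_penalty_term(critic, x, xhat, y, u)
    total = nn.neg(gap) + weights.lambda_gp * penalty
    parts = {
        "wasserstein": gap.item(),
        "penalty": penalty.item(),
        "grad_norm": grad_norm.item(),
        "total": total.item(),
    }
    return total, parts


# ---------------------------------------------------------------------------
# numpy-facing evaluation wrappers
# ---------------------------------------------------------------------------

def _img_t(images: np.ndarray) -> nn.Tensor:
    return nn.Tensor(to_nchw(images))

def _mask_t(masks: np.ndarray) -> nn.Tensor:
    m = np.asarray(masks, dtype=np.float64)
    if m.ndim == 2:
        m = m[None]
    return nn.Tensor(m[:, None])


def wasserstein_loss(critic, x: np.ndarray, xhat: np.ndarray, y: np.ndarray) -> float:
    """Batch-mean D(x,y) - D(xhat,y) for numpy image/mask arrays."""
    return wasserstein_gap(critic, _img_t(x), _img_t(xhat), _mask_t(y)).item()


def gradient_penalty(critic, x: np.ndarray, xhat: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Batch-mean (||grad D at interpolates|| - 1)^2 with seeded interpolation."""
    xt, ht = _img_t(x), _img_t(xhat)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x69]))
    u = rng.uniform(0.0, 1.0, size=xt.shape[0])
    penalty, _ = gradient_penalty_term(critic, xt, ht, _mask_t(y), u)
    return penalty.item()


def severity_loss(grader, x: np.ndarray, xhat: np.ndarray) -> float:
    """Batch-mean absolute difference of grade estimates."""
    return severity_gap(grader, _img_t(x), _img_t(xhat)).item()


def perceptual_loss(feature_net, layer: str, x: np.ndarray, xhat: np.ndarray) -> float:
    """Element-averaged squared feature distance at stage ``layer``."""
    return perceptual_gap(feature_net, layer, _img_t(x), _img_t(xhat)).item()


def generator_loss(critic, grader, feature_net, layer: str, x: np.ndarray,
                   xhat: np.ndarray, y: np.ndarray, weights: LossWeights) -> tuple[float, dict]:
    total, parts = generator_objective(critic, grader, feature_net, layer,
                                       _img_t(x), _img_t(xhat), _mask_t(y), weights)
    return total.item(), parts


def critic_loss(critic, x: np.ndarray, xhat: np.ndarray, y: np.ndarray,
                weights: LossWeights, seed: int) -> tuple[float, dict]:
    xt, ht = _img_t(x), _img_t(xhat)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x69]))
    u = rng.uniform(0.0, 1.0, size=xt.shape[0])
    total, parts = critic_objective(critic, xt, ht, _mask_t(y), weights, u)
    return total.item(), parts


def generate(gen: GeneratorModel, vessel_mask: np.ndarray, lesions: np.ndarray,
             z: np.ndarray) -> np.ndarray:
    """Synthesise image(s) from a vessel mask, lesion descriptor and noise.

    ``z`` is (Z,) for a single image or (N,Z) for a batch; output is
    HxWx3 (or NxHxWx3) in [0,1].
    """
    cond = condition_stack(vessel_mask, lesions)
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    if single:
        z = z[None]
    if cond.shape[0] == 1 and z.shape[0] > 1:
        cond = np.repeat(cond, z.shape[0], axis=0)
    out = gen.forward(nn.Tensor(cond), nn.Tensor(z)).data
    imgs = np.transpose(out, (0, 2, 3, 1))
    return imgs[0] if single else imgs
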