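"""Conditional WGAN-GP models and the Eq. 1-5 loss system."""

import numpy as np
import pytest

from fundusgan import nn
from fundusgan.gan import (CriticModel, GeneratorModel, LossWeights,
                           condition_stack, critic_loss, generate,
                           generator_loss, gradient_penalty,
                           gradient_penalty_term, perceptual_loss,
                           severity_loss, wasserstein_loss)
from fundusgan.grader import GraderModel

RNG = np.random.default_rng(0)
X = RNG.uniform(0, 1, (4, 16, 16, 3))
XH = RNG.uniform(0, 1, (4, 16, 16, 3))
Y = RNG.uniform(0, 1, (4, 16, 16))


class _ConstCritic:
    def __init__(self, c):
        self.c = c

    def score(self, x, y):
        return nn.Tensor(np.full(x.shape[0], self.c)) + nn.tsum(x * 0.0, axis=(1, 2, 3))


class _SlopeCritic:
    """score = <w, x>; input-gradient norm equals ||w||."""

    def __init__(self, w):
        self.w = w  # (3,H,W)

    def score(self, x, y):
        return nn.tsum(x * nn.Tensor(self.w[None]), axis=(1, 2, 3))


class _StubGrader:
    """Returns queued grade vectors, one per forward call."""

    def __init__(self, *vals):
        self.vals = iter(vals)

    def forward(self, x):
        return nn.Tensor(np.asarray(next(self.vals), dtype=np.float64))


# -- wasserstein ------------------------------------------------------------

def test_wasserstein_constant_critic_is_zero():
    assert wasserstein_loss(_ConstCritic(3.7), X, XH, Y) == pytest.approx(0.0, abs=1e-12)


def test_wasserstein_separating_stub_is_one():
    class Stub:
        calls = 0

        def score(self, x, y):
            Stub.calls += 1
            val = 1.0 if Stub.calls == 1 else 0.0
            return nn.Tensor(np.full(x.shape[0], val)) + nn.tsum(x * 0.0, axis=(1, 2, 3))

    assert wasserstein_loss(Stub(), X, XH, Y) == pytest.approx(1.0, abs=1e-12)


def test_wasserstein_matches_per_pair_mean():
    critic = CriticModel(side=16, base_width=4, init_seed=2)
    got = wasserstein_loss(critic, X, XH, Y)
    per_pair = []
    for i in range(4):
        xi = nn.Tensor(np.transpose(X[i:i + 1], (0, 3, 1, 2)))
        hi = nn.Tensor(np.transpose(XH[i:i + 1], (0, 3, 1, 2)))
        yi = nn.Tensor(Y[i:i + 1][:, None])
        per_pair.append(critic.score(xi, yi).item() - critic.score(hi, yi).item())
    assert got == pytest.approx(np.mean(per_pair), abs=1e-6)


# -- gradient penalty --------------------------------------------------------

def _unit_w():
    # four entries of 0.5: ||w||^2 = 1 exactly under any summation order
    w = np.zeros((3, 16, 16))
    w[0, 0, 0] = w[1, 3, 4] = w[2, 7, 9] = w[0, 15, 15] = 0.5
    return w


def test_gp_unit_slope_critic_is_exactly_zero():
    assert gradient_penalty(_SlopeCritic(_unit_w()), X, XH, Y, seed=0) == 0.0


def test_gp_slope_two_critic_is_exactly_one():
    assert gradient_penalty(_SlopeCritic(2 * _unit_w()), X, XH, Y, seed=0) == 1.0


def test_gp_gradient_norm_matches_finite_differences():
    critic = CriticModel(side=16, base_width=4, init_seed=1)
    u = np.random.default_rng(5).uniform(size=4)
    xt = nn.Tensor(np.transpose(X, (0, 3, 1, 2)))
    ht = nn.Tensor(np.transpose(XH, (0, 3, 1, 2)))
    yt = nn.Tensor(Y[:, None])
    _, mean_norm = gradient_penalty_term(critic, xt, ht, yt, u)

    # finite-difference gradient of the critic score at the interpolates
    x_tilde = u[:, None, None, None] * xt.data + (1 - u[:, None, None, None]) * ht.data
    eps = 1e-5
    norms = []
    for i in range(4):
        g = np.zeros_like(x_tilde[i])
        for idx in np.ndindex(*x_tilde[i].shape):
            p = x_tilde[i].copy()
            p[idx] += eps
            q = x_tilde[i].copy()
            q[idx] -= eps
            sp = critic.score(nn.Tensor(p[None]), nn.Tensor(Y[i:i + 1][:, None])).item()
            sq = critic.score(nn.Tensor(q[None]), nn.Tensor(Y[i:i + 1][:, None])).item()
            g[idx] = (sp - sq) / (2 * eps)
        norms.append(np.sqrt((g**2).sum()))
    assert abs(mean_norm.item() - np.mean(norms)) <= 1e-3


# -- severity / perceptual ----------------------------------------------------

def test_severity_zero_on_identical_inputs(quick_grader, dataset40):
    img = dataset40[0].image[None]
    assert severity_loss(quick_grader, img, img) == 0.0


def test_severity_stub_pairs():
    x = np.zeros((3, 16, 16, 3))
    assert severity_loss(_StubGrader([4.0], [1.0]), x[:1], x[:1]) == pytest.approx(3.0)
    got = severity_loss(_StubGrader([0.0, 2.0, 4.0], [1.0, 2.0, 0.0]), x, x)
    assert got == pytest.approx(5.0 / 3.0, abs=1e-12)


def test_perceptual_zero_on_identical_inputs(quick_grader):
    assert perceptual_loss(quick_grader, "stage2", X, X) == 0.0


def test_perceptual_identity_layer_equals_pixel_mse(quick_grader):
    pl = perceptual_loss(quick_grader, "input", X, XH)
    assert pl == pytest.approx(np.mean((X - XH) ** 2), abs=1e-12)


def test_perceptual_matches_manual_feature_difference():
    net = GraderModel(side=16, init_seed=8)
    pl = perceptual_loss(net, "stage1", X, XH)
    fx = net.features(X, "stage1")
    fh = net.features(XH, "stage1")
    assert pl == pytest.approx(np.mean((fx - fh) ** 2), abs=1e-6)


# -- generator / critic objectives --------------------------------------------

def _gen_setup():
    critic = CriticModel(side=16, base_width=4, init_seed=1)
    grader = GraderModel(side=16, init_seed=9)
    return critic, grader


def test_generator_loss_reduces_to_adversarial_when_weights_zero():
    critic, grader = _gen_setup()
    total, parts = generator_loss(critic, grader, grader, "stage2", X, XH, Y,
                                  LossWeights(wp=0.0, ws=0.0))
    assert total == parts["adversarial"]
    xh_t = nn.Tensor(np.transpose(XH, (0, 3, 1, 2)))
    adv = -critic.score(xh_t, nn.Tensor(Y[:, None])).data.mean()
    assert total == pytest.approx(adv, abs=1e-12)


def test_generator_loss_decomposition_exact():
    critic, grader = _gen_setup()
    w = LossWeights(wp=0.7, ws=1.3)
    total, parts = generator_loss(critic, grader, grader, "stage2", X, XH, Y, w)
    assert total == parts["adversarial"] + w.wp * parts["perceptual"] + w.ws * parts["severity"]


def test_generator_loss_linear_in_wp():
    critic, grader = _gen_setup()
    t1, p1 = generator_loss(critic, grader, grader, "stage2", X, XH, Y, LossWeights(wp=1.0))
    t2, p2 = generator_loss(critic, grader, grader, "stage2", X, XH, Y, LossWeights(wp=2.0))
    assert p1["perceptual"] == p2["perceptual"]
    assert t2 - t1 == pytest.approx(p1["perceptual"], abs=1e-9)


def test_critic_loss_zero_for_constant_critic_without_penalty():
    total, _ = critic_loss(_ConstCritic(2.0), X, XH, Y, LossWeights(lambda_gp=0.0), seed=0)
    assert total == pytest.approx(0.0, abs=1e-12)


def test_critic_loss_unit_slope_has_zero_penalty():
    critic = _SlopeCritic(_unit_w())
    total, parts = critic_loss(critic, X, XH, Y, LossWeights(lambda_gp=10.0), seed=3)
    assert parts["penalty"] == 0.0
    assert total == pytest.approx(-wasserstein_loss(critic, X, XH, Y), abs=1e-12)


def test_critic_loss_seeded_reproducible():
    critic = CriticModel(side=16, base_width=4, init_seed=4)
    a = critic_loss(critic, X, XH, Y, LossWeights(), seed=11)
    b = critic_loss(critic, X, XH, Y, LossWeights(), seed=11)
    assert a[0] == b[0] and a[1] == b[1]


# -- models and generation -----------------------------------------------------

def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(wp=-1.0)
    with pytest.raises(ValueError):
        LossWeights(lambda_gp=float("nan"))


def test_condition_stack_shape():
    lesions = RNG.integers(0, 2, (4, 2, 16, 16)).astype(float)
    cond = condition_stack(Y, lesions)
    assert cond.shape == (4, 3, 16, 16)
    assert np.array_equal(cond[:, 0], Y)
    assert np.array_equal(cond[:, 1:], lesions)


def test_generate_deterministic_and_bounded():
    gen = GeneratorModel(side=16, base_width=4, z_dim=8, init_seed=1)
    lesions = RNG.integers(0, 2, (2, 16, 16)).astype(float)
    z = RNG.normal(size=8)
    a = generate(gen, Y[0], lesions, z)
    b = generate(gen, Y[0], lesions, z)
    assert np.array_equal(a, b)
    assert a.shape == (16, 16, 3)
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_generate_varies_with_z():
    gen = GeneratorModel(side=16, base_width=4, z_dim=8, init_seed=1)
    lesions = RNG.integers(0, 2, (2, 16, 16)).astype(float)
    zs = RNG.normal(size=(5, 8))
    imgs = generate(gen, Y[0], lesions, zs)
    assert imgs.shape == (5, 16, 16, 3)
    hashes = {img.tobytes() for img in imgs}
    assert len(hashes) == 5


def test_critic_score_shape_checks():
    critic = CriticModel(side=16, base_width=4, init_seed=0)
    with pytest.raises(ValueError):
        critic.score(nn.Tensor(np.zeros((1, 3, 8, 8))), nn.Tensor(np.zeros((1, 1, 8, 8))))
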