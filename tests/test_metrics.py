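"""FID, MSE, SSIM and the evaluation pipeline."""

import numpy as np
import pytest

from fundusgan.metrics import (GaussianStats, MetricReport, embed, evaluate,
                               fid, fid_from_images, mse, reports_to_csv, ssim)


def _stats(mu, sigma, n=10):
    return GaussianStats(mu=np.asarray(mu, dtype=np.float64),
                         sigma=np.atleast_2d(np.asarray(sigma, dtype=np.float64)),
                         n=n)


# -- FID -----------------------------------------------------------------------

def test_fid_equal_stats_is_zero():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(4, 4))
    sigma = a @ a.T + np.eye(4)
    mu = rng.normal(size=4)
    assert abs(fid(_stats(mu, sigma), _stats(mu, sigma))) <= 1e-8


def test_fid_mean_shift_identity_covariance():
    got = fid(_stats([0.0, 0.0], np.eye(2)), _stats([3.0, 4.0], np.eye(2)))
    assert abs(got - 25.0) <= 1e-8


def test_fid_scalar_variances():
    got = fid(_stats([0.0], [[4.0]]), _stats([0.0], [[1.0]]))
    assert abs(got - 1.0) <= 1e-8


def test_fid_symmetry_and_nonnegativity():
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        s1 = _stats(rng.normal(size=3), a @ a.T + 0.1 * np.eye(3))
        s2 = _stats(rng.normal(size=3), b @ b.T + 0.1 * np.eye(3))
        assert abs(fid(s1, s2) - fid(s2, s1)) <= 1e-8
        assert fid(s1, s2) >= -1e-8


def test_fid_rejects_non_psd():
    with pytest.raises(ValueError):
        fid(_stats([0.0, 0.0], [[1.0, 0.0], [0.0, -1.0]]),
            _stats([0.0, 0.0], np.eye(2)))


def test_fid_rejects_dimension_mismatch():
    with pytest.raises(ValueError):
        fid(_stats([0.0], [[1.0]]), _stats([0.0, 0.0], np.eye(2)))


# -- embedding -----------------------------------------------------------------

def test_from_features_hand_computed_covariance():
    stats = GaussianStats.from_features(np.array([[0.0], [1.0]]))
    assert stats.mu[0] == 0.5
    assert stats.sigma[0, 0] == pytest.approx(0.5)  # n-1 denominator at n=2


def test_from_features_requires_two_samples():
    with pytest.raises(ValueError):
        GaussianStats.from_features(np.ones((1, 3)))


def test_embed_identical_images_give_zero_fid(quick_grader):
    img = np.random.default_rng(2).uniform(size=(64, 64, 3))
    images = np.stack([img] * 5)
    feats = embed(images, quick_grader)
    assert np.allclose(feats, feats[0])
    stats = GaussianStats.from_features(feats)
    assert abs(fid(stats, stats)) <= 1e-8


def test_embed_order_invariant(quick_grader, dataset40):
    images = np.stack([s.image for s in dataset40[:8]])
    perm = np.random.default_rng(3).permutation(8)
    a = GaussianStats.from_features(embed(images, quick_grader))
    b = GaussianStats.from_features(embed(images[perm], quick_grader))
    assert np.allclose(a.mu, b.mu) and np.allclose(a.sigma, b.sigma)


# -- MSE -----------------------------------------------------------------------

def test_mse_identities():
    x = np.random.default_rng(4).uniform(size=(5, 5, 3))
    assert mse(x, x) == 0.0
    assert mse(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]])) == 0.5


def test_mse_matches_brute_force_loop():
    rng = np.random.default_rng(5)
    for _ in range(100):
        x = rng.uniform(size=(6, 7, 3))
        y = rng.uniform(size=(6, 7, 3))
        acc = 0.0
        for i in range(6):
            for j in range(7):
                for c in range(3):
                    acc += (x[i, j, c] - y[i, j, c]) ** 2
        assert abs(mse(x, y) - acc / (6 * 7 * 3)) <= 1e-12


def test_mse_shape_mismatch():
    with pytest.raises(ValueError):
        mse(np.zeros((2, 2)), np.zeros((3, 3)))


# -- SSIM ----------------------------------------------------------------------

def test_ssim_self_is_one_both_modes():
    x = np.random.default_rng(6).uniform(size=(32, 32, 3))
    assert ssim(x, x, mode="windowed") == 1.0
    assert ssim(x, x, mode="global") == 1.0


def test_ssim_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(3):
        x = rng.uniform(size=(16, 16))
        y = rng.uniform(size=(16, 16))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)


def test_ssim_global_constant_images_closed_form():
    a = np.zeros((8, 8))
    b = np.ones((8, 8))
    # zero variances: SSIM = (2*0*1 + C1)(0 + C2) / ((0+1+C1)(0+C2)) = C1/(1+C1)
    expected = 1e-4 / (1.0 + 1e-4)
    assert abs(ssim(a, b, mode="global") - expected) <= 1e-9


def test_ssim_windowed_equals_global_for_constants():
    a = np.full((16, 16), 0.3)
    b = np.full((16, 16), 0.8)
    assert ssim(a, b, mode="windowed") == pytest.approx(
        ssim(a, b, mode="global"), abs=1e-12)


def test_ssim_bounded_and_below_one_when_different():
    rng = np.random.default_rng(8)
    x = rng.uniform(size=(16, 16))
    y = rng.uniform(size=(16, 16))
    v = ssim(x, y)
    assert v <= 1.0
    assert v < 1.0


def test_ssim_window_larger_than_image_rejected():
    x = np.zeros((8, 8))
    with pytest.raises(ValueError, match="window"):
        ssim(x, x, mode="windowed", window=11)


# -- evaluation pipeline ---------------------------------------------------------

def test_evaluate_self_comparison(quick_grader, dataset40):
    real = np.stack([s.image for s in dataset40[:6]])
    rep = evaluate(real, lambda z_seed: real, repeats=1, seed=0,
                   method="identity", grader=quick_grader)
    assert rep.mse_mean == 0.0
    assert rep.ssim_mean == 1.0
    assert abs(rep.fid_mean) <= 1e-8
    assert rep.n == 6


def test_evaluate_seeded_reproducible(quick_grader, dataset40):
    real = np.stack([s.image for s in dataset40[:6]])

    def gen_batch(z_seed):
        rng = np.random.default_rng(z_seed)
        return np.clip(real + 0.05 * rng.normal(size=real.shape), 0, 1)

    a = evaluate(real, gen_batch, repeats=2, seed=5, method="m", grader=quick_grader)
    b = evaluate(real, gen_batch, repeats=2, seed=5, method="m", grader=quick_grader)
    assert a == b
    assert a.mse_sd > 0.0  # two distinct repeats


def test_evaluate_rejects_unpaired_counts(quick_grader, dataset40):
    real = np.stack([s.image for s in dataset40[:6]])
    with pytest.raises(ValueError):
        evaluate(real, lambda z: real[:5], repeats=1, seed=0,
                 method="m", grader=quick_grader)


def test_reports_to_csv_round_trip(tmp_path, quick_grader, dataset40):
    real = np.stack([s.image for s in dataset40[:6]])
    rep = evaluate(real, lambda z: real, repeats=1, seed=0,
                   method="bilinear", grader=quick_grader)
    path = tmp_path / "report.csv"
    reports_to_csv([rep], path)
    lines = path.read_text().splitlines()
    assert lines[0] == ",".join(MetricReport.COLUMNS)
    assert lines[1].startswith("bilinear,")
    assert len(lines) == 2


def test_fid_from_images_custom_embedder():
    rng = np.random.default_rng(9)
    a = rng.uniform(size=(10, 4, 4, 3))
    chan_mean = lambda imgs: imgs.mean(axis=(1, 2))
    assert abs(fid_from_images(a, a, chan_mean)) <= 1e-8
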