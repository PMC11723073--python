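"""Image-quality metrics: FID, MSE and SSIM, plus the evaluation pipeline.

FID is computed between Gaussian fits of embedded image sets:
``||mu_r - mu_g||^2 + Tr(Sigma_r + Sigma_g - 2 (Sigma_r Sigma_g)^{1/2})``.
The default embedder pools the stand-in grader's designated feature
stage over space; any callable mapping an image batch to feature rows
can be plugged in instead (e.g. an externally supplied Inception
network).  FID values are only comparable within one embedder, so
reports record which was used.

SSIM uses C1 = (0.01 L)^2, C2 = (0.03 L)^2 with dynamic range L = 1 and
is offered in two modes: ``windowed`` (11x11 Gaussian window, sigma 1.5,
Gaussian-weighted local moments, reflect padding, averaged over all
positions) and ``global`` (whole image as a single window).  Colour
images are reduced to grayscale by the channel mean first.  MSE and
SSIM operate on [0,1] floats before any 8-bit quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grader import DEFAULT_FEATURE_LAYER, GraderModel

SSIM_C1 = 0.01 ** 2
SSIM_C2 = 0.03 ** 2
_EIG_TOL = -1e-10


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianStats:
    """Mean and covariance of an embedded sample set."""

    mu: np.ndarray  # (d,)
    sigma: np.ndarray  # (d, d)
    n: int

    @classmethod
    def from_features(cls, features: np.ndarray) -> "GaussianStats":
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2:
            raise ValueError(f"expected (n, d) feature rows, got shape {features.shape}")
        if features.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a covariance")
        mu = features.mean(axis=0)
        sigma = np.cov(features, rowvar=False)  # n-1 denominator
        return cls(mu=mu, sigma=np.atleast_2d(sigma), n=features.shape[0])


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w.min() < _EIG_TOL:
        raise ValueError(
            f"covariance has eigenvalue {w.min():.3e} below tolerance {_EIG_TOL:.0e};"
            " not a valid covariance matrix")
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def fid(real: GaussianStats, gen: GaussianStats) -> float:
    """Frechet distance between two Gaussian fits.

    The trace cross term uses the eigendecomposition of the symmetrised
    product ``S Sigma_g S`` with ``S = sqrt(Sigma_r)``; eigenvalues in
    ``[-1e-10, 0)`` (numerical residue) are clipped to zero, anything
    more negative raises.
    """
    if real.mu.shape != gen.mu.shape:
        raise ValueError("embedding dimensions differ between the two sets")
    diff = real.mu - gen.mu
    s = _psd_sqrt(real.sigma)
    inner = s @ gen.sigma @ s
    w = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    if w.min() < _EIG_TOL:
        raise ValueError(
            f"cross-covariance product eigenvalue {w.min():.3e} below tolerance;"
            " embeddings are numerically degenerate")
    w = np.clip(w, 0.0, None)
    tr = np.trace(real.sigma) + np.trace(gen.sigma) - 2.0 * np.sqrt(w).sum()
    return float(diff @ diff + tr)


def embed(images: np.ndarray, grader: GraderModel,
          layer: str = DEFAULT_FEATURE_LAYER, batch: int = 25) -> np.ndarray:
    """Default FID embedding: grader stage features, average-pooled over space."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    rows = []
    for i in range(0, images.shape[0], batch):
        feats = grader.features(images[i:i + batch], layer)  # (b, C, H', W')
        rows.append(feats.mean(axis=(2, 3)))
    return np.concatenate(rows, axis=0)


def fid_from_images(real_images: np.ndarray, gen_images: np.ndarray,
                    embedder) -> float:
    """FID between image sets under ``embedder`` (images -> feature rows)."""
    return fid(GaussianStats.from_features(embedder(real_images)),
               GaussianStats.from_features(embedder(gen_images)))


# ---------------------------------------------------------------------------
# MSE / SSIM
# ---------------------------------------------------------------------------

def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error over all elements of two equal-shape arrays."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(np.mean(d * d))


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return img.mean(axis=2)
    if img.ndim == 2:
        return img
    raise ValueError(f"expected HxW or HxWxC image, got shape {img.shape}")


def ssim(x: np.ndarray, y: np.ndarray, mode: str = "windowed",
         window: int = 11, sigma: float = 1.5,
         c1: float = SSIM_C1, c2: float = SSIM_C2) -> float:
    """Structural similarity of two images in [0,1] (dynamic range L = 1).

    ``windowed`` computes Gaussian-weighted local moments (window 11,
    sigma 1.5, reflect padding) and averages the per-pixel SSIM map;
    ``global`` treats the whole image as a single window with plain
    (population) moments.
    """
    gx, gy = _to_gray(x), _to_gray(y)
    if gx.shape != gy.shape:
        raise ValueError(f"shape mismatch: {gx.shape} vs {gy.shape}")
    if mode == "global":
        mx, my = gx.mean(), gy.mean()
        vx, vy = gx.var(), gy.var()
        cxy = ((gx - mx) * (gy - my)).mean()
    elif mode == "windowed":
        if window % 2 != 1 or window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if window > min(gx.shape):
            raise ValueError(
                f"window {window} larger than image {gx.shape}; use a smaller"
                " window or global mode")
        radius = window // 2
        def filt(a):
            return ndimage.gaussian_filter(a, sigma=sigma, mode="reflect",
                                           truncate=radius / sigma)
        mx, my = filt(gx), filt(gy)
        vx = filt(gx * gx) - mx * mx
        vy = filt(gy * gy) - my * my
        cxy = filt(gx * gy) - mx * my
    else:
        raise ValueError(f"unknown ssim mode {mode!r}; use 'windowed' or 'global'")
    num = (2.0 * mx * my + c1) * (2.0 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


# ---------------------------------------------------------------------------
# evaluation pipeline (one per-kernel comparison row at toy scale)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricReport:
    """FID/MSE/SSIM summary with dispersion over generation repeats."""

    method: str
    mse_mean: float
    mse_sd: float
    ssim_mean: float
    ssim_sd: float
    fid_mean: float
    fid_sd: float
    n: int
    embedder: str

    COLUMNS = ("method", "mse_mean", "mse_sd", "ssim_mean", "ssim_sd",
               "fid_mean", "fid_sd", "n", "embedder")

    def row(self) -> dict:
        return {k: getattr(self, k) for k in self.COLUMNS}


def evaluate(real_images: np.ndarray, generate_batch, repeats: int, seed: int,
             method: str, embedder=None, grader: GraderModel | None = None,
             ssim_mode: str = "windowed") -> MetricReport:
    """Score a generator against a fixed real set.

    ``generate_batch(z_seed) -> (n, H, W, 3)`` must synthesise one image
    per real sample under the same conditions; repeats differ only in
    the noise seed (``seed + r``).  MSE/SSIM are paired per sample and
    averaged; FID is computed per repeat between the full sets.
    ``embedder`` defaults to the grader's pooled stage features.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    real_images = np.asarray(real_images, dtype=np.float64)
    if embedder is None:
        if grader is None:
            raise ValueError("provide an embedder or a grader for the default embedding")
        embedder_name = f"grader:{DEFAULT_FEATURE_LAYER}"
        embedder = lambda imgs: embed(imgs, grader)
    else:
        embedder_name = getattr(embedder, "name", "custom")
    real_stats = GaussianStats.from_features(embedder(real_images))

    mses, ssims, fids = [], [], []
    for r in range(repeats):
        gen_images = np.asarray(generate_batch(seed + r), dtype=np.float64)
        if gen_images.shape != real_images.shape:
            raise ValueError(
                f"generated set shape {gen_images.shape} != real {real_images.shape}")
        mses.append(np.mean([mse(a, b) for a, b in zip(real_images, gen_images)]))
        ssims.append(np.mean([ssim(a, b, mode=ssim_mode)
                              for a, b in zip(real_images, gen_images)]))
        fids.append(fid(real_stats, GaussianStats.from_features(embedder(gen_images))))

    def sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    return MetricReport(method=method,
                        mse_mean=float(np.mean(mses)), mse_sd=sd(mses),
                        ssim_mean=float(np.mean(ssims)), ssim_sd=sd(ssims),
                        fid_mean=float(np.mean(fids)), fid_sd=sd(fids),
                        n=int(real_images.shape[0]), embedder=embedder_name)


def reports_to_csv(reports, path) -> None:
    """Write MetricReports as the standard report CSV."""
    import csv
    import os
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MetricReport.COLUMNS)
        writer.writeheader()
        for rep in reports:
            writer.writerow(rep.row())
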