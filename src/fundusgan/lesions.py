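"""Saliency-based lesion descriptor extraction.

The pathological conditioning input for the generator is a pair of
binary maps marking lesion locations at two scales.  They are distilled
from the severity grader by backpropagating its scalar grade output to
the input pixels: the channel-summed absolute input gradient is the
saliency map, which is then Gaussian-smoothed at a fine and a coarse
standard deviation and binarised at a per-image quantile threshold.

Conventions (documented defaults, all overridable):

* saliency operator: plain input gradient, channel-summed absolute
  value — the simplest choice, and exactly checkable against finite
  differences;
* Gaussian smoothing truncated at 4 sigma, kernel renormalised,
  reflect padding;
* binarisation at the empirical ``1 - q`` quantile (default q = 0.02)
  computed over field-of-view pixels only (outside the fundus disk the
  image is structurally black); values tied with the threshold are
  included;
* an identically-zero saliency map yields empty masks at any q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from ._util import to_nchw
from .grader import GraderModel


@dataclass
class LesionDescriptor:
    """Two-scale binary lesion maps plus the raw saliency they came from."""

    fine: np.ndarray  # H x W, {0,1}
    coarse: np.ndarray  # H x W, {0,1}
    saliency: np.ndarray  # H x W, >= 0
    params: tuple[float, float, float]  # (sigma_fine, sigma_coarse, q)

    def stack(self) -> np.ndarray:
        """(2, H, W) float array in generator conditioning order (fine, coarse)."""
        return np.stack([self.fine, self.coarse]).astype(np.float64)


def saliency_map(model: GraderModel, image: np.ndarray) -> np.ndarray:
    """Channel-summed absolute input gradient of the scalar grade output."""
    x = nn.Tensor(to_nchw(image), requires_grad=True)
    pred = model.forward(x)
    g = nn.grad(nn.tsum(pred), x)
    return np.abs(g.data[0]).sum(axis=0)


def infer_fov(image: np.ndarray, threshold: float = 1e-3) -> np.ndarray:
    """Field-of-view support: pixels with any channel above ``threshold``.

    Fundus photographs are black outside the circular camera aperture;
    for images with no black surround this returns the full frame.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        return image.max(axis=2) > threshold
    return image > threshold


def gaussian_smooth(saliency: np.ndarray, sigma: float) -> np.ndarray:
    """Discrete Gaussian filter, truncated at 4 sigma, reflect-padded."""
    return ndimage.gaussian_filter(np.asarray(saliency, dtype=np.float64),
                                   sigma=sigma, mode="reflect", truncate=4.0)


def _binarize(smoothed: np.ndarray, fov: np.ndarray, q: float) -> np.ndarray:
    if not smoothed.any():
        return np.zeros(smoothed.shape, dtype=np.uint8)
    threshold = np.quantile(smoothed[fov], 1.0 - q)
    return ((smoothed >= threshold) & fov).astype(np.uint8)


def extract(model: GraderModel, image: np.ndarray, sigma_fine: float = 1.0,
            sigma_coarse: float = 4.0, q: float = 0.02,
            fov: np.ndarray | None = None) -> LesionDescriptor:
    """Lesion descriptor maps ``D(x)`` for one image.

    The saliency map is smoothed at ``sigma_fine`` and ``sigma_coarse``
    and each result is binarised at its own ``1 - q`` quantile over
    field-of-view pixels (ties included).  ``fov`` defaults to the
    support inferred from the image.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quantile q must lie strictly between 0 and 1")
    if not 0.0 < sigma_fine < sigma_coarse:
        raise ValueError("need 0 < sigma_fine < sigma_coarse")
    sal = saliency_map(model, image)
    if fov is None:
        fov = infer_fov(image)
    fov = np.asarray(fov, dtype=bool)
    if not fov.any():
        fov = np.ones(sal.shape, dtype=bool)
    fine = _binarize(gaussian_smooth(sal, sigma_fine), fov, q)
    coarse = _binarize(gaussian_smooth(sal, sigma_coarse), fov, q)
    return LesionDescriptor(fine=fine, coarse=coarse, saliency=sal,
                            params=(float(sigma_fine), float(sigma_coarse), float(q)))
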