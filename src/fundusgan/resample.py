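"""Separable image resampling with a configurable kernel family.

The resize configuration (kernel name plus antialias flag) is a first-class
method variant in this package: the same :class:`ResampleSpec` drives both
dataset preprocessing and the generator's decoder upsampling, so one spec
defines one comparable method configuration end to end.

Conventions (fixed, and relied on by the brute-force oracle tests):

* half-pixel centres — destination index ``d`` maps to source coordinate
  ``s = (d + 0.5) * in/out - 0.5``;
* kernels: nearest (round-half-up toward the larger index), bilinear
  (tent, support 1), bicubic (Keys cubic, a = -0.5, support 2), mitchell
  (Mitchell-Netravali, B = C = 1/3, support 2), lanczos5 (sinc windowed
  by sinc, support 5);
* antialiasing stretches the kernel by the downscale factor when and only
  when downscaling; upsampling is unaffected by the flag;
* edges handled by clamping source indices (weight accumulates at the
  border sample); per-destination weights renormalised to sum to 1;
* output clipped to [0, 1] (cubic and Lanczos kernels overshoot).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

KERNELS = ("nearest", "bilinear", "bicubic", "mitchell", "lanczos5")


@dataclass(frozen=True)
class ResampleSpec:
    """A named resampling kernel plus antialias flag."""

    kernel: str = "bilinear"
    antialias: bool = False

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(
                f"unknown resampling kernel {self.kernel!r}; expected one of {KERNELS}"
            )

    @classmethod
    def parse(cls, label: str) -> "ResampleSpec":
        """Parse labels like ``"bicubic"`` or ``"bilinear+antialias"``."""
        name, _, suffix = label.partition("+")
        if suffix not in ("", "antialias"):
            raise ValueError(f"unknown resample modifier {suffix!r} in {label!r}")
        return cls(kernel=name.strip(), antialias=suffix == "antialias")

    @property
    def label(self) -> str:
        return self.kernel + ("+antialias" if self.antialias else "")


# ---------------------------------------------------------------------------
# kernel functions (continuous, unit support scale)
# ---------------------------------------------------------------------------

def _tent(t: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - np.abs(t))


def _keys_cubic(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    t = np.abs(t)
    t2, t3 = t * t, t * t * t
    out = np.where(
        t <= 1.0,
        (a + 2) * t3 - (a + 3) * t2 + 1.0,
        np.where(t < 2.0, a * t3 - 5 * a * t2 + 8 * a * t - 4 * a, 0.0),
    )
    return out


def _mitchell(t: np.ndarray, B: float = 1 / 3, C: float = 1 / 3) -> np.ndarray:
    t = np.abs(t)
    t2, t3 = t * t, t * t * t
    p1 = ((12 - 9 * B - 6 * C) * t3 + (-18 + 12 * B + 6 * C) * t2 + (6 - 2 * B)) / 6.0
    p2 = (
        (-B - 6 * C) * t3
        + (6 * B + 30 * C) * t2
        + (-12 * B - 48 * C) * t
        + (8 * B + 24 * C)
    ) / 6.0
    return np.where(t < 1.0, p1, np.where(t < 2.0, p2, 0.0))


def _lanczos(t: np.ndarray, a: float = 5.0) -> np.ndarray:
    out = np.sinc(t) * np.sinc(t / a)
    return np.where(np.abs(t) < a, out, 0.0)


_KERNEL_FNS = {
    "bilinear": (_tent, 1.0),
    "bicubic": (_keys_cubic, 2.0),
    "mitchell": (_mitchell, 2.0),
    "lanczos5": (_lanczos, 5.0),
}


# ---------------------------------------------------------------------------
# weight matrices
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def weight_matrix(in_size: int, out_size: int, kernel: str, antialias: bool) -> np.ndarray:
    """Dense (out_size, in_size) resampling matrix for one axis.

    Rows sum to 1; source indices outside the image clamp to the border
    sample. ``nearest`` places a single unit weight per row and ignores
    the antialias flag.
    """
    if in_size < 1 or out_size < 1:
        raise ValueError("image sizes must be positive")
    if in_size == out_size:
        # unchanged axes pass through untouched; relevant for smoothing
        # kernels (Mitchell) that would otherwise blur at identity scale
        return np.eye(out_size)
    ratio = in_size / out_size  # >1 downscale, <1 upscale
    d = np.arange(out_size)
    s = (d + 0.5) * ratio - 0.5

    W = np.zeros((out_size, in_size))
    if kernel == "nearest":
        idx = np.floor(s + 0.5).astype(int)  # half rounds toward larger index
        idx = np.clip(idx, 0, in_size - 1)
        W[d, idx] = 1.0
        return W

    fn, support = _KERNEL_FNS[kernel]
    stretch = ratio if (antialias and ratio > 1.0) else 1.0
    sup = support * stretch
    for row in range(out_size):
        lo = int(np.ceil(s[row] - sup))
        hi = int(np.floor(s[row] + sup))
        src = np.arange(lo, hi + 1)
        wts = fn((src - s[row]) / stretch)
        total = wts.sum()
        if total == 0.0:  # pragma: no cover - degenerate, support always >= 1
            W[row, int(np.clip(round(s[row]), 0, in_size - 1))] = 1.0
            continue
        wts = wts / total
        np.add.at(W[row], np.clip(src, 0, in_size - 1), wts)
    return W


def resize(img: np.ndarray, out_h: int, out_w: int, spec: ResampleSpec) -> np.ndarray:
    """Resample ``img`` (H×W or H×W×C, values in [0,1]) to ``out_h × out_w``."""
    if out_h < 1 or out_w < 1:
        raise ValueError("output size must be at least 1x1")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError("expected an HxW or HxWxC array")
    h, w = img.shape[:2]
    Wr = weight_matrix(h, out_h, spec.kernel, spec.antialias)
    Wc = weight_matrix(w, out_w, spec.kernel, spec.antialias)
    if img.ndim == 2:
        out = Wr @ img @ Wc.T
    else:
        out = np.einsum("oh,hwc,pw->opc", Wr, img, Wc, optimize=True)
    return np.clip(out, 0.0, 1.0)


def preprocess(img: np.ndarray, side: int, spec: ResampleSpec) -> np.ndarray:
    """Standardise an image to ``side × side`` for the synthesis pipeline."""
    if side < 8:
        raise ValueError("side must be at least 8")
    return resize(img, side, side, spec)
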