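"""Small array-layout helpers shared across modules."""

from __future__ import annotations

import numpy as np


def to_nchw(images: np.ndarray) -> np.ndarray:
    """HxWxC / NxHxWxC float arrays -> NxCxHxW (adds batch dim if absent)."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[:, :, None]
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4:
        raise ValueError(f"expected image array of 2-4 dims, got shape {images.shape}")
    return np.transpose(images, (0, 3, 1, 2))


def from_nchw(batch: np.ndarray) -> np.ndarray:
    """NxCxHxW -> NxHxWxC."""
    return np.transpose(np.asarray(batch), (0, 2, 3, 1))
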