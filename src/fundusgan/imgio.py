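"""Raster image I/O: 8-bit PNG/JPEG to and from float arrays in [0, 1]."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np


def load_image(path) -> np.ndarray:
    """Decode an 8-bit image file to a float64 H×W×C array in [0, 1].

    Grayscale files come back with C=1; an alpha channel, if present, is
    dropped. Raises ``IOError`` (with the path in the message) on missing
    or undecodable files.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise decoder errors
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise IOError(f"cannot read image {path!r}: unsupported shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise IOError(f"cannot read image {path!r}: expected 8-bit data, got {arr.dtype}")
    return arr.astype(np.float64) / 255.0


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] float array as an 8-bit PNG/JPEG.

    Values already on the 8-bit lattice (k/255) round-trip exactly
    through :func:`load_image`.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3 or img.shape[2] not in (1, 3):
        raise ValueError(f"expected HxW or HxWxC image with C in {{1,3}}, got {img.shape}")
    data = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    if data.shape[2] == 1:
        data = data[:, :, 0]
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    iio.imwrite(path, data)
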