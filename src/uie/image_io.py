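"""Raster I/O and the floating-point working representation.

An image is carried through the pipeline as a float64 numpy array of shape
(H, W, 3) with channels ordered red, green, blue and a nominal intensity
range of [0, 255].  Intermediate stages may legitimately exceed that range
(the color balance multiplies channels up); values are only clipped and
rounded by :func:`quantize`, which is applied at file output and before any
histogram-based metric.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_image", "quantize", "validate_rgb"]


class ImageFormatError(ValueError):
    """Raised when a file decodes to something other than an 8-bit raster."""


def validate_rgb(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check that *img* is a finite (H, W, 3) float array; return it as float64."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name}: expected shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name}: degenerate dimensions {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite pixel values")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit raster image as a float64 (H, W, 3) array.

    Grayscale images are promoted to three identical channels; an alpha
    channel, if present, is dropped.  Values are the decoded 8-bit
    integers converted to reals, unchanged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    data = iio.imread(path)
    if data.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected 8-bit samples, got dtype {data.dtype}"
        )
    if data.ndim == 2:
        data = np.stack([data, data, data], axis=-1)
    elif data.ndim == 3 and data.shape[2] == 4:
        data = data[:, :, :3]
    elif data.ndim != 3 or data.shape[2] != 3:
        raise ImageFormatError(f"{path}: unsupported layout {data.shape}")
    return data.astype(np.float64)


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Quantize *img* to 8 bits and write it; format chosen by extension.

    PNG, TIFF and PPM are lossless; JPEG is supported but lossy, so round
    trips are only exact for the lossless formats.
    """
    arr = quantize(img).astype(np.uint8)
    iio.imwrite(path, arr)


def quantize(img: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero; idempotent.

    After clipping all values are non-negative, so half-away-from-zero
    reduces to floor(x + 0.5).  Stated explicitly because numpy's default
    rounding is half-to-even.
    """
    arr = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantize: non-finite pixel values")
    return np.floor(np.clip(arr, 0.0, 255.0) + 0.5)
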