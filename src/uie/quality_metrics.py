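"""Discrete entropy, MSE and PSNR for 8-bit image pairs.

Entropy is the Shannon entropy of the 256-level gray histogram,
H = -sum p(x) log2 p(x); it proxies information content.  MSE is the mean
squared intensity difference over all pixels and channels, and PSNR is
the standard peak-signal form 10*log10((2^B - 1)^2 / MSE) in dB for
B = 8 bits per sample.  All metrics operate on quantized data so the
histograms are well defined.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np

from uie.image_io import validate_rgb

__all__ = ["QualityReport", "entropy", "mse", "psnr", "write_report"]

#: sentinel PSNR for identical images (MSE == 0)
PSNR_INF = math.inf

_LUMA = np.array([0.299, 0.587, 0.114])


def _require_8bit(img: np.ndarray, name: str) -> np.ndarray:
    arr = validate_rgb(img, name=name)
    if np.any(arr < 0) or np.any(arr > 255) or np.any(arr != np.floor(arr)):
        raise ValueError(
            f"{name}: metrics require quantized 8-bit values; call quantize() first"
        )
    return arr


def _hist_entropy(values: np.ndarray) -> float:
    counts = np.bincount(values.astype(np.int64).ravel(), minlength=256)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def entropy(img: np.ndarray, channel_mode: str = "per_channel_mean") -> float:
    """Discrete entropy in bits over k = 256 gray levels.

    ``per_channel_mean`` (default) averages the three per-channel
    entropies; ``grayscale`` first collapses to luminance with weights
    (0.299, 0.587, 0.114), rounded to integers.
    """
    arr = _require_8bit(img, "entropy input")
    if channel_mode == "per_channel_mean":
        return float(
            np.mean([_hist_entropy(arr[:, :, c]) for c in range(3)])
        )
    if channel_mode == "grayscale":
        gray = np.floor(arr @ _LUMA + 0.5)
        return _hist_entropy(gray)
    raise ValueError(f"unknown channel_mode {channel_mode!r}")


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared error over all pixels and all three channels."""
    a = _require_8bit(ref, "ref")
    b = _require_8bit(test, "test")
    if a.shape != b.shape:
        raise ValueError(f"mse: shape mismatch {a.shape} vs {b.shape}")
    d = a - b
    return float(np.mean(d * d))


def psnr(mse_value: float, bits_per_sample: int = 8) -> float:
    """Peak signal-to-noise ratio, 10*log10((2^B - 1)^2 / MSE) in dB.

    MSE of zero returns the +infinity sentinel rather than erroring.
    """
    if mse_value < 0:
        raise ValueError(f"mse must be non-negative, got {mse_value}")
    if mse_value == 0:
        return PSNR_INF
    peak = (1 << bits_per_sample) - 1
    return 10.0 * math.log10(peak * peak / mse_value)


@dataclass(frozen=True)
class QualityReport:
    """Entropy/MSE/PSNR triple for an (original, enhanced) image pair."""

    entropy: float
    mse: float
    psnr: float
    bits_per_sample: int = 8

    def as_dict(self) -> dict:
        return asdict(self)


def write_report(
    rows: list[dict], path: str | os.PathLike, fmt: str = "csv"
) -> None:
    """Write evaluation rows (image, method, entropy, mse, psnr) as CSV or JSON."""
    fields = ["image", "method", "entropy", "mse", "psnr"]
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: row.get(k) for k in fields})
    else:
        raise ValueError(f"unknown report format {fmt!r}")
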