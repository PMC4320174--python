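"""HSV color correction: percentile-limited stretching of S and V.

After contrast correction the image is moved to the hue-saturation-value
(hexcone) model and the saturation and value planes are stretched so that
their 1st and 99th percentiles land on 0 and 1, clipping the tails.
Limiting the stretch to the 1%/99% percentiles (of the data, not of the
intensity range) keeps a few outlying pixels from dictating the mapping
and bounds the mass driven into saturation at each end.  Hue is never
modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from uie.image_io import quantize, validate_rgb

__all__ = ["HSVImage", "rgb_to_hsv", "hsv_to_rgb", "percentile_stretch", "correct_color"]


@dataclass(frozen=True)
class HSVImage:
    """Hue in degrees [0, 360), saturation and value in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray


def rgb_to_hsv(img: np.ndarray) -> HSVImage:
    """Standard hexcone conversion of a clipped 8-bit-range RGB image."""
    arr = quantize(validate_rgb(img)) / 255.0
    hsv = _skcolor.rgb2hsv(arr)
    return HSVImage(
        hue=hsv[:, :, 0] * 360.0,
        saturation=hsv[:, :, 1],
        value=hsv[:, :, 2],
    )


def hsv_to_rgb(img: HSVImage) -> np.ndarray:
    """Inverse hexcone conversion back to the [0, 255] RGB representation."""
    hsv = np.stack(
        [
            np.mod(img.hue, 360.0) / 360.0,
            np.clip(img.saturation, 0.0, 1.0),
            np.clip(img.value, 0.0, 1.0),
        ],
        axis=-1,
    )
    return _skcolor.hsv2rgb(hsv) * 255.0


def percentile_stretch(
    plane: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0
) -> np.ndarray:
    """Affinely map the [p_lo, p_hi] percentile span of a [0,1] plane to [0,1].

    Percentiles use the linear-interpolation definition.  Output is
    clip((x - q_lo) / (q_hi - q_lo), 0, 1); a near-constant plane whose
    percentiles coincide is returned unchanged with a warning.
    """
    if p_lo >= p_hi:
        raise ValueError(f"require p_lo < p_hi, got ({p_lo}, {p_hi})")
    arr = np.asarray(plane, dtype=np.float64)
    q_lo, q_hi = np.percentile(arr, [p_lo, p_hi])
    if q_hi == q_lo:
        warnings.warn(
            "percentile_stretch: degenerate plane left unchanged", stacklevel=2
        )
        return arr.copy()
    return np.clip((arr - q_lo) / (q_hi - q_lo), 0.0, 1.0)


def correct_color(
    img: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0
) -> np.ndarray:
    """Stretch S and V between their percentile limits; hue passes through."""
    hsv = rgb_to_hsv(img)
    return hsv_to_rgb(
        HSVImage(
            hue=hsv.hue,
            saturation=percentile_stretch(hsv.saturation, p_lo, p_hi),
            value=percentile_stretch(hsv.value, p_lo, p_hi),
        )
    )
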