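"""Composition of the dual-intensity image pair by pixel-wise averaging.

The bright (lower-region-stretched) and dark (upper-region-stretched)
images derive from the same source, so no registration is involved: the
composite is the plain per-pixel-location mean, computed in real
arithmetic before any quantization.
"""

from __future__ import annotations

import numpy as np

from uie.image_io import validate_rgb

__all__ = ["compose_average"]


def compose_average(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Per-pixel mean of two equally sized images."""
    a = validate_rgb(img_a, name="img_a")
    b = validate_rgb(img_b, name="img_b")
    if a.shape != b.shape:
        raise ValueError(
            f"compose_average: shape mismatch {a.shape} vs {b.shape}"
        )
    return (a + b) / 2.0
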