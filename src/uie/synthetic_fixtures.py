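"""Synthetic underwater scenes with a controllable degradation model.

Real shallow-water photographs show a strong blue-green cast (red light is
absorbed within a few meters), a compressed dynamic range from veiling
light, coexisting bright sand and dark shadow regions, and mild sensor
noise.  :func:`make_scene` renders a clean reef-like scene — a smooth
illumination gradient, textured elliptical coral/fish blobs with distinct
hues, a bright sand band and a dark shadow — and :func:`degrade` applies
per-channel attenuation, additive veiling light, contrast compression
about the channel mean, and Gaussian noise.  Everything is a deterministic
function of the spec's integer seed (numpy ``default_rng`` with
SeedSequence-derived streams: [seed, 0] for the scene, [seed, 1] for the
noise), so paired clean/degraded fixtures are reproducible bitwise.

The model is deliberately a gain + veil + compression + noise composite,
not a physical radiative-transfer simulation: the enhancement pipeline
only needs inputs carrying the cast/low-contrast signature.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from uie.image_io import quantize, validate_rgb

__all__ = ["SceneSpec", "make_scene", "degrade", "make_pair", "ellipse_mask"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic underwater degradation model.

    ``attenuation`` is the fraction of signal retained per channel (red
    lowest — red light dies first in water); ``veil`` is the blue-green
    veiling light color in [0, 255] mixed in with weight ``veil_weight``;
    ``contrast_compression`` shrinks each channel's range about its mean;
    ``noise_sd`` is the Gaussian sensor-noise standard deviation in
    intensity levels.
    """

    height: int = 120
    width: int = 160
    attenuation: tuple[float, float, float] = (0.25, 0.70, 0.85)
    veil: tuple[float, float, float] = (10.0, 130.0, 185.0)
    veil_weight: float = 0.35
    contrast_compression: float = 0.55
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be positive")
        if not all(0.0 <= a <= 1.0 for a in self.attenuation):
            raise ValueError("attenuation fractions must lie in [0, 1]")
        if not all(0.0 <= v <= 255.0 for v in self.veil):
            raise ValueError("veil color must lie in [0, 255]")
        if not (0.0 <= self.veil_weight <= 1.0):
            raise ValueError("veil_weight must lie in [0, 1]")
        if not (0.0 < self.contrast_compression <= 1.0):
            raise ValueError("contrast_compression must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def ellipse_mask(
    height: int,
    width: int,
    cy: float,
    cx: float,
    ry: float,
    rx: float,
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside an axis-aligned ellipse."""
    yy, xx = np.mgrid[0:height, 0:width]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


# distinct blob hues: coral orange, fish yellow, plant green, anemone purple
_BLOB_COLORS = np.array(
    [
        [210.0, 120.0, 60.0],
        [220.0, 200.0, 70.0],
        [70.0, 170.0, 90.0],
        [150.0, 80.0, 170.0],
    ]
)


def make_scene(spec: SceneSpec) -> np.ndarray:
    """Render the clean (pre-degradation) scene; quantized 8-bit values.

    Composite of a vertical illumination gradient with low-frequency
    texture, four textured elliptical blobs, a bright sand band along the
    bottom, and one dark shadow ellipse — guaranteeing bright and dark
    areas in every scene and at least 64 distinct levels per channel.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    v = yy / max(h - 1, 1)
    u = xx / max(w - 1, 1)

    # water-column illumination: brighter near the surface (top)
    img = np.empty((h, w, 3))
    base = np.array([150.0, 160.0, 170.0])
    for c in range(3):
        img[:, :, c] = base[c] - 70.0 * v + 15.0 * u

    # low-frequency texture with seeded phases
    for _ in range(3):
        fy, fx = rng.uniform(1.5, 5.0, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(4.0, 9.0)
        wave = amp * np.sin(2 * np.pi * fy * v + py) * np.cos(2 * np.pi * fx * u + px)
        img += wave[:, :, None]

    # textured coral/fish blobs
    for color in _BLOB_COLORS:
        cy = rng.uniform(0.15, 0.75) * h
        cx = rng.uniform(0.1, 0.9) * w
        ry = rng.uniform(0.06, 0.14) * h
        rx = rng.uniform(0.06, 0.16) * w
        mask = ellipse_mask(h, w, cy, cx, ry, rx)
        tex = 1.0 + 0.15 * np.sin(0.55 * yy + rng.uniform(0, 2 * np.pi)) * np.cos(
            0.45 * xx + rng.uniform(0, 2 * np.pi)
        )
        for c in range(3):
            img[:, :, c] = np.where(mask, color[c] * tex, img[:, :, c])

    # bright sand band along the bottom
    sand = v > 0.82
    ripple = 12.0 * np.sin(0.5 * xx + 1.7) * np.sin(0.3 * yy)
    sand_color = np.array([225.0, 215.0, 190.0])
    for c in range(3):
        img[:, :, c] = np.where(sand, sand_color[c] + ripple, img[:, :, c])

    # one dark shadow region so every scene has a genuinely dark area
    sh = ellipse_mask(
        h,
        w,
        rng.uniform(0.3, 0.6) * h,
        rng.uniform(0.2, 0.8) * w,
        0.08 * h,
        0.10 * w,
    )
    img[sh] *= 0.22

    return quantize(img)


def degrade(clean: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Apply the underwater degradation model to a clean scene.

    Per channel c: compress the range about the channel mean by
    ``contrast_compression``, then
    out = (1 - w) * attenuation_c * compressed + w * veil_c + noise,
    clipped to [0, 255] and quantized.  Identity parameters
    (attenuation 1, veil_weight 0, compression 1, noise 0) leave the
    image unchanged.
    """
    arr = validate_rgb(clean)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out = np.empty_like(arr)
    w = spec.veil_weight
    for c in range(3):
        ch = arr[:, :, c]
        m = ch.mean()
        compressed = m + spec.contrast_compression * (ch - m)
        out[:, :, c] = (1.0 - w) * spec.attenuation[c] * compressed + w * spec.veil[c]
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    return quantize(out)


def make_pair(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (clean, degraded) pair for one spec."""
    clean = make_scene(spec)
    return clean, degrade(clean, spec)


def write_pair(spec: SceneSpec, out_dir: str | os.PathLike, stem: str) -> None:
    """Write clean/degraded PNGs plus a JSON sidecar of the spec."""
    from uie.image_io import write_image

    os.makedirs(out_dir, exist_ok=True)
    clean, degraded = make_pair(spec)
    write_image(os.path.join(out_dir, f"{stem}_clean.png"), clean)
    write_image(os.path.join(out_dir, f"{stem}_degraded.png"), degraded)
    with open(os.path.join(out_dir, f"{stem}_spec.json"), "w") as fh:
        fh.write(spec.to_json())
        fh.write("\n")
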