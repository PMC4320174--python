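"""End-to-end enhancement pipeline, HE baseline, and evaluation.

Stage order of the full chain: channel decomposition -> median-referenced
Von Kries color balance -> per-channel global min-max stretch ->
per-channel mean split and dual-region Rayleigh stretch -> recomposition
of the three lower-mapped channels into a bright image and the three
upper-mapped channels into a dark image -> pixel-wise average of the pair
-> HSV saturation/value percentile stretch -> quantization.  The split
mean is recomputed on the globally stretched channel, so the division
point reflects the renormalized histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from uie.color_balance import apply_color_balance
from uie.composition import compose_average
from uie.dual_rayleigh_stretch import (
    RayleighParams,
    dual_stretch_channel,
    global_stretch,
)
from uie.hsv_correction import correct_color
from uie.image_io import quantize, validate_rgb, write_image
from uie.quality_metrics import QualityReport, entropy, mse, psnr

__all__ = ["PipelineConfig", "enhance", "histogram_equalization", "evaluate"]

logger = logging.getLogger("uie")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the enhancement chain.

    Defaults reproduce the described pipeline end to end; the skip flags
    are ablation switches that drop the color-balance or HSV stage.
    """

    alpha: float = 0.4
    mode: str = "quantile"
    sv_percentiles: tuple[float, float] = (1.0, 99.0)
    skip_color_balance: bool = False
    skip_hsv: bool = False

    def rayleigh_params(self) -> RayleighParams:
        return RayleighParams(alpha=self.alpha, mode=self.mode)


def enhance(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    save_stages: str | None = None,
) -> np.ndarray:
    """Run the full enhancement chain; returns a quantized 8-bit image.

    Degenerate channels (constant after some stage) surface as warnings
    from the stage operations and never abort the chain.  With
    ``save_stages`` set, each intermediate image is written to that
    directory as a PNG for inspection.
    """
    cfg = config or PipelineConfig()
    arr = validate_rgb(img)
    params = cfg.rayleigh_params()

    def dump(stage: str, stage_img: np.ndarray) -> None:
        if save_stages is not None:
            import os

            os.makedirs(save_stages, exist_ok=True)
            write_image(f"{save_stages}/{stage}.png", stage_img)

    if not cfg.skip_color_balance:
        arr = apply_color_balance(arr)
        dump("1_color_balance", arr)

    lower = np.empty_like(arr)
    upper = np.empty_like(arr)
    for c in range(3):
        stretched = global_stretch(arr[:, :, c])
        lo_map, up_map = dual_stretch_channel(stretched, params)
        lower[:, :, c] = lo_map
        upper[:, :, c] = up_map
        logger.debug(
            "channel %d: stretched mean %.2f, clip fractions lo %.3f / up %.3f",
            c,
            stretched.mean(),
            float(np.mean(lo_map == 255.0)),
            float(np.mean(up_map == 0.0)),
        )
    dump("2_lower_stretched", lower)
    dump("3_upper_stretched", upper)

    composed = compose_average(lower, upper)
    dump("4_composed", composed)

    if not cfg.skip_hsv:
        composed = correct_color(composed, *cfg.sv_percentiles)
        dump("5_hsv_corrected", composed)

    return quantize(composed)


def histogram_equalization(img: np.ndarray) -> np.ndarray:
    """Classic per-channel 8-bit histogram equalization baseline.

    Uses the cdf-min normalized lookup table
    L(k) = round(255 * (cdf(k) - cdf_min) / (1 - cdf_min)), which leaves
    an image with a uniform histogram (and a two-level {0, 255} image)
    unchanged.
    """
    arr = quantize(validate_rgb(img)).astype(np.int64)
    out = np.empty_like(arr, dtype=np.float64)
    n = arr.shape[0] * arr.shape[1]
    for c in range(3):
        counts = np.bincount(arr[:, :, c].ravel(), minlength=256)
        cdf = np.cumsum(counts) / n
        cdf_min = cdf[np.nonzero(counts)[0][0]]
        if cdf_min == 1.0:  # constant channel: already a single level
            out[:, :, c] = arr[:, :, c]
            continue
        lut = np.floor(255.0 * (cdf - cdf_min) / (1.0 - cdf_min) + 0.5)
        out[:, :, c] = lut[arr[:, :, c]]
    return out


def evaluate(original: np.ndarray, enhanced: np.ndarray) -> QualityReport:
    """Entropy of the enhanced image plus MSE/PSNR against the original."""
    orig = quantize(validate_rgb(original, name="original"))
    enh = quantize(validate_rgb(enhanced, name="enhanced"))
    if orig.shape != enh.shape:
        raise ValueError(
            f"evaluate: shape mismatch {orig.shape} vs {enh.shape}"
        )
    m = mse(orig, enh)
    return QualityReport(entropy=entropy(enh), mse=m, psnr=psnr(m))
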