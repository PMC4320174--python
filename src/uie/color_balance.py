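"""Median-referenced Von Kries color balancing.

The classical Von Kries correction holds the dominant (highest-mean) color
cast channel fixed and scales the other two up toward it, which for a
strong blue cast forces a very large gain on the red channel and can
falsify object colors.  The variant implemented here instead takes the
channel whose mean is the *median* of the three channel means as the
reference: the minimum-mean channel is multiplied by
A = median / min and the maximum-mean channel by B = median / max, so all
three channel means coincide at the median afterwards and neither gain
strays far from 1.

No clipping is performed here: scaled values may exceed 255 and are
carried as reals, because the subsequent global stretch renormalizes each
channel and clipping would break the mean-equalization property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from uie.image_io import validate_rgb

__all__ = ["ChannelGains", "channel_mean", "compute_gains", "apply_color_balance"]

_CHANNELS = ("red", "green", "blue")


class DegenerateChannelError(ValueError):
    """A channel mean is non-positive and cannot be rescaled to a positive target."""


@dataclass(frozen=True)
class ChannelGains:
    """Per-channel multipliers of the balancing step.

    ``reference`` is the median-mean channel (gain 1); ``gain_min`` (>= 1
    for distinct means) applies to the minimum-mean channel and
    ``gain_max`` (<= 1) to the maximum-mean channel.
    """

    reference: str
    gain_min: float
    gain_max: float
    min_channel: str
    max_channel: str

    def as_vector(self) -> np.ndarray:
        """Gains in (R, G, B) order."""
        g = np.ones(3)
        g[_CHANNELS.index(self.min_channel)] = self.gain_min
        g[_CHANNELS.index(self.max_channel)] = self.gain_max
        return g


def channel_mean(channel: np.ndarray) -> float:
    """Arithmetic mean of a 2-D channel over all M*N pixels."""
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("channel_mean: empty channel")
    return float(arr.mean())


def compute_gains(r_avg: float, g_avg: float, b_avg: float) -> ChannelGains:
    """Gains that pull the min- and max-mean channels to the median mean.

    Ties are broken by ranking channels on (mean, fixed order R<G<B); the
    middle rank is the reference, so equal means give identity gains.
    """
    means = (r_avg, g_avg, b_avg)
    if any(m <= 0 for m in means):
        raise DegenerateChannelError(
            f"channel means must be positive, got {means}"
        )
    order = sorted(range(3), key=lambda i: (means[i], i))
    i_min, i_med, i_max = order
    med = means[i_med]
    return ChannelGains(
        reference=_CHANNELS[i_med],
        gain_min=med / means[i_min],
        gain_max=med / means[i_max],
        min_channel=_CHANNELS[i_min],
        max_channel=_CHANNELS[i_max],
    )


def apply_color_balance(img: np.ndarray) -> np.ndarray:
    """Scale the min- and max-mean channels so all means equal the median mean.

    Single pass: gains are computed from the input image and applied once.
    Output values are not clipped.
    """
    arr = validate_rgb(img)
    gains = compute_gains(
        channel_mean(arr[:, :, 0]),
        channel_mean(arr[:, :, 1]),
        channel_mean(arr[:, :, 2]),
    )
    return arr * gains.as_vector()
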