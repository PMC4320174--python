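"""Global stretching and mean-split dual-region Rayleigh stretching.

Each channel is first stretched affinely so its observed [min, max] covers
the full dynamic range [0, 255].  The channel mean (recomputed on the
stretched values) then splits the intensity axis into a lower region
[min, mean] and an upper region [mean, max], and each region is
independently mapped onto the full range so that the mapped intensities
follow a Rayleigh distribution truncated to [0, 255].  Applying both maps
to every pixel (values outside a region saturate at the endpoints) yields
two complete images — one bright, one dark — whose average is the
contrast-corrected result.

The Rayleigh target is a histogram specification: the normalized position
u of a pixel inside its region is pushed through the inverse CDF of a
Rayleigh distribution with scale sigma = alpha * 255, truncated so u = 0
and u = 1 land exactly on 0 and 255.  A "literal" mode that instead
evaluates the Rayleigh *density* at the affinely stretched value (and then
rescales to [0, 255]) is retained for comparison; it is non-monotonic and
exists only as a fidelity experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from uie.color_balance import channel_mean

__all__ = [
    "RegionBounds",
    "RayleighParams",
    "global_stretch",
    "rayleigh_cdf",
    "rayleigh_inverse_cdf",
    "rayleigh_region_stretch",
    "split_at_mean",
    "dual_stretch_channel",
]


class DegenerateRegionError(ValueError):
    """Raised when a stretch region has zero width."""


@dataclass(frozen=True)
class RegionBounds:
    """Observed channel extremes and the mean used as division point.

    The lower region is [lo, split], the upper region [split, hi].
    ``degenerate`` flags a constant channel (lo == split == hi).
    """

    lo: float
    hi: float
    split: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.split <= self.hi):
            raise ValueError(
                f"require lo <= split <= hi, got ({self.lo}, {self.split}, {self.hi})"
            )

    @property
    def degenerate(self) -> bool:
        return self.hi == self.lo


@dataclass(frozen=True)
class RayleighParams:
    """Rayleigh scale and mapping mode for region stretching.

    ``alpha`` is the Rayleigh scale as a fraction of the output range, so
    the absolute scale is sigma = alpha * (o_max - o_min); the default
    0.4 puts sigma at 102 on an 8-bit range, keeping the mode of the
    truncated distribution near mid-range.  ``mode`` selects the default
    monotonic quantile mapping or the literal density-transfer variant.
    """

    alpha: float = 0.4
    mode: str = "quantile"
    o_min: float = 0.0
    o_max: float = 255.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.o_min >= self.o_max:
            raise ValueError("o_min must be below o_max")
        if self.mode not in ("quantile", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def sigma(self) -> float:
        return self.alpha * (self.o_max - self.o_min)


def global_stretch(
    channel: np.ndarray, o_min: float = 0.0, o_max: float = 255.0
) -> np.ndarray:
    """Affine min-max stretch of a channel onto [o_min, o_max].

    P_out = (P_in - i_min) * (o_max - o_min) / (i_max - i_min) + o_min
    with i_min/i_max the observed channel extremes.  A constant channel
    cannot be stretched; it is returned unchanged with a warning so flat
    fixtures do not abort batch runs.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("global_stretch: empty channel")
    i_min = arr.min()
    i_max = arr.max()
    if i_max == i_min:
        warnings.warn(
            "global_stretch: constant channel left unchanged", stacklevel=2
        )
        return arr.copy()
    return (arr - i_min) * (o_max - o_min) / (i_max - i_min) + o_min


def rayleigh_cdf(x, sigma: float):
    """Rayleigh CDF, F(x) = 1 - exp(-x^2 / (2 sigma^2)) for x >= 0."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("rayleigh_cdf: x must be >= 0")
    out = 1.0 - np.exp(-(x * x) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def rayleigh_inverse_cdf(u, sigma: float):
    """Rayleigh quantile function, F^{-1}(u) = sigma * sqrt(-2 ln(1 - u)).

    Defined for u in [0, 1); u = 1 maps to infinity and is rejected so
    callers must truncate the target distribution instead.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u = np.asarray(u, dtype=np.float64)
    if np.any(u < 0) or np.any(u >= 1):
        raise ValueError("rayleigh_inverse_cdf: u must lie in [0, 1)")
    out = sigma * np.sqrt(-2.0 * np.log1p(-u))
    return float(out) if out.ndim == 0 else out


def rayleigh_region_stretch(
    channel: np.ndarray,
    bounds_lo: float,
    bounds_hi: float,
    params: RayleighParams | None = None,
) -> np.ndarray:
    """Map the whole channel through the [bounds_lo, bounds_hi] region map.

    Quantile mode: u = clip((P - lo)/(hi - lo), 0, 1) and
    y = F^{-1}(u * F(R)) with F the Rayleigh CDF at scale sigma =
    alpha * R, R = o_max - o_min — i.e. histogram specification onto a
    Rayleigh distribution truncated to the output range.  Monotonic, with
    u = 0 -> o_min and u = 1 -> o_max exactly; pixels below the region
    saturate at o_min and above it at o_max.

    Literal mode: evaluate the Rayleigh density transfer
    t = (s / sigma^2) * exp(-s^2 / (2 sigma^2)) at the affinely
    stretched value s = R * (P - lo) / (hi - lo), then rescale the
    channel's t-values linearly onto [o_min, o_max].
    """
    if params is None:
        params = RayleighParams()
    if bounds_hi <= bounds_lo:
        raise DegenerateRegionError(
            f"region [{bounds_lo}, {bounds_hi}] has non-positive width"
        )
    arr = np.asarray(channel, dtype=np.float64)
    rng = params.o_max - params.o_min
    sigma = params.sigma
    u = np.clip((arr - bounds_lo) / (bounds_hi - bounds_lo), 0.0, 1.0)
    if params.mode == "quantile":
        f_top = rayleigh_cdf(rng, sigma)
        return params.o_min + rayleigh_inverse_cdf(u * f_top, sigma)
    # literal Eq-style density transfer, rescaled post hoc
    s = u * rng
    t = (s / sigma**2) * np.exp(-(s * s) / (2.0 * sigma * sigma))
    t_min, t_max = t.min(), t.max()
    if t_max == t_min:
        warnings.warn(
            "rayleigh_region_stretch: flat literal transfer, returning o_min",
            stacklevel=2,
        )
        return np.full_like(t, params.o_min)
    return (t - t_min) * rng / (t_max - t_min) + params.o_min


def split_at_mean(channel: np.ndarray) -> RegionBounds:
    """Channel extremes plus the channel mean as the region split point."""
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("split_at_mean: empty channel")
    bounds = RegionBounds(
        lo=float(arr.min()), hi=float(arr.max()), split=channel_mean(arr)
    )
    if bounds.degenerate:
        warnings.warn("split_at_mean: constant channel", stacklevel=2)
    return bounds


def dual_stretch_channel(
    channel: np.ndarray, params: RayleighParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Map a channel through both region maps; returns (lower, upper) images.

    The lower map stretches [min, mean] to the full range (pixels at or
    above the mean saturate at 255, so this is the brighter output); the
    upper map stretches [mean, max] (pixels at or below the mean map to
    0, the darker output).  Pointwise, lower >= upper.
    """
    if params is None:
        params = RayleighParams()
    bounds = split_at_mean(channel)
    if bounds.degenerate:
        arr = np.asarray(channel, dtype=np.float64)
        return arr.copy(), arr.copy()
    lower = rayleigh_region_stretch(channel, bounds.lo, bounds.split, params)
    upper = rayleigh_region_stretch(channel, bounds.split, bounds.hi, params)
    return lower, upper
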