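"""HSV pseudo-color rendering of dynamics maps.

Three channels encode three aspects of the per-pixel fluctuation
spectrum: hue is the centroid frequency fmean (8 Hz -> 0, red; 13 Hz
-> 0.66, blue), saturation is the reciprocal fluctuation bandwidth
1/fstd (narrow-band motion is vivid, broadband noise washes out), and
value is the fluctuation amplitude STD (strong motion is bright).
Viable tissue renders red-yellow, necrotic tissue blue-green, and
background noise dark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = ["ColorMapSpec", "hue_of", "render_pseudocolor"]


@dataclass(frozen=True)
class ColorMapSpec:
    """Parameters of the fmean/fstd/STD -> HSV mapping.

    ``f_lo``/``f_hi`` bound the hue ramp in Hz; ``hue_max`` is the hue
    assigned at ``f_hi`` (0.66 = blue on the HSV circle); ``sat_norm``
    and ``val_norm`` are the robust percentiles at which 1/fstd and STD
    saturate to 1.
    """

    f_lo: float = 8.0
    f_hi: float = 13.0
    hue_max: float = 0.66
    sat_norm: float = 99.0
    val_norm: float = 99.0

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if not 0.0 < self.hue_max <= 1.0:
            raise ValueError("hue_max must be in (0, 1]")
        for p in (self.sat_norm, self.val_norm):
            if not 0.0 < p <= 100.0:
                raise ValueError("percentiles must be in (0, 100]")


def hue_of(fmean, spec: ColorMapSpec = ColorMapSpec()):
    """Hue channel value(s) for given fmean: linear ramp, clamped to the band."""
    f = np.clip(np.asarray(fmean, dtype=np.float64), spec.f_lo, spec.f_hi)
    return (f - spec.f_lo) / (spec.f_hi - spec.f_lo) * spec.hue_max


def _robust_scale(raster: np.ndarray, percentile: float) -> np.ndarray:
    """Scale to [0, 1], clipping at the given percentile of positive values."""
    pos = raster[raster > 0]
    if pos.size == 0:
        return np.zeros_like(raster)
    hi = np.percentile(pos, percentile)
    if hi <= 0:
        return np.zeros_like(raster)
    return np.clip(raster / hi, 0.0, 1.0)


def render_pseudocolor(
    maps,
    spec: ColorMapSpec = ColorMapSpec(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Render a DynamicsMaps object to an RGB float raster in [0, 1].

    Saturation is the robust-normalised reciprocal of fstd; pixels with
    fstd == 0 (zero total power) get saturation 0 rather than blowing
    up.  Pixels outside ``mask`` (when given) are black.
    """
    h = hue_of(maps.fmean, spec)
    with np.errstate(divide="ignore"):
        inv_bw = np.where(maps.fstd > 0, 1.0 / np.maximum(maps.fstd, 1e-300), 0.0)
    s = _robust_scale(inv_bw, spec.sat_norm)
    v = _robust_scale(maps.std, spec.val_norm)
    hsv = np.stack([h, s, v], axis=-1)
    rgb = hsv_to_rgb(hsv)
    if mask is not None:
        rgb = np.where(mask[..., None], rgb, 0.0)
    return np.clip(rgb, 0.0, 1.0)


def to_uint8(rgb: np.ndarray) -> np.ndarray:
    """Convert a [0, 1] float RGB raster to 8-bit for export."""
    return np.round(np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)
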