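"""Per-pixel power-spectrum dynamics maps.

The dynamic-OCT contrast mechanism: each pixel of a repeated B-scan
series carries an intensity time series whose fluctuation spectrum
reflects sub-resolution cellular motion.  Per pixel we estimate a
one-sided Welch power spectral density P(f) and reduce it to

* ``fmean`` — the PSD-weighted centroid frequency,
  sum_i (P_i / sum_j P_j) * f_i  (low in viable tissue, high in
  necrotic/noise-dominated regions);
* ``fstd``  — the PSD-weighted frequency standard deviation
  sqrt(sum w_i f_i^2 - (sum w_i f_i)^2), the fluctuation bandwidth;
* ``std``   — the per-pixel temporal standard deviation of intensity
  (population form, 1/N), the fluctuation amplitude.

Frames are first normalised by their spatial mean to suppress
frame-to-frame illumination instability, and the per-pixel temporal
mean (DC) is removed before spectral estimation so that the static
backscatter level does not drag every centroid toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io import AcquisitionMeta, TimeSeriesStack

__all__ = [
    "WelchParams",
    "PowerSpectrum",
    "DynamicsMaps",
    "normalize_frames",
    "pixel_psd",
    "mean_frequency",
    "frequency_std",
    "intensity_std",
    "compute_dynamics_maps",
    "smooth_map",
]


@dataclass(frozen=True)
class WelchParams:
    """Parameters of the per-pixel Welch PSD estimate.

    Defaults: 256-frame Hann segments with 50% overlap give three
    averaged segments from a 512-frame series and a frequency
    resolution of fs/256 (about 0.22 Hz at 56 fps).
    """

    segment_length: int = 256
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: bool = True

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def noverlap(self) -> int:
        return int(self.segment_length * self.overlap_fraction)

    def resolved(self, n_frames: int) -> "WelchParams":
        """Clip the segment length to the series length."""
        if self.segment_length > n_frames:
            raise ValueError(
                f"segment_length {self.segment_length} exceeds series "
                f"length {n_frames}"
            )
        return self


@dataclass
class PowerSpectrum:
    """A single pixel's one-sided PSD on its frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if self.freqs.shape != self.psd.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and psd must be 1D of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")


@dataclass
class DynamicsMaps:
    """Co-registered fmean / fstd / STD rasters for one cross-section."""

    fmean: np.ndarray
    fstd: np.ndarray
    std: np.ndarray
    params: WelchParams = field(default_factory=WelchParams)
    frame_rate: float = 56.0
    smoothed: bool = False

    def __post_init__(self) -> None:
        if not (self.fmean.shape == self.fstd.shape == self.std.shape):
            raise ValueError("fmean, fstd and std must share one shape")


def normalize_frames(stack: TimeSeriesStack) -> TimeSeriesStack:
    """Divide each frame by its own spatial mean intensity.

    Removes frame-to-frame gain/illumination instability; every output
    frame has spatial mean exactly 1 (to floating tolerance).
    """
    means = stack.values.mean(axis=(1, 2))
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"frame {bad[0]} has non-positive spatial mean ({means[bad[0]]}); "
            "cannot normalize"
        )
    return stack.with_values(stack.values / means[:, None, None])


def _welch_nd(
    values: np.ndarray, frame_rate: float, params: WelchParams
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD along axis 0 of a (time, ...) array.

    Detrending removes the *whole-series* temporal mean per pixel before
    segmentation (DC exclusion), not per-segment means.
    """
    if params.detrend:
        values = values - values.mean(axis=0, keepdims=True)
    freqs, psd = signal.welch(
        values,
        fs=frame_rate,
        window=params.window,
        nperseg=params.segment_length,
        noverlap=params.noverlap,
        detrend=False,
        return_onesided=True,
        scaling="density",
        axis=0,
    )
    return freqs, psd


def pixel_psd(
    series: np.ndarray, meta: AcquisitionMeta, params: WelchParams | None = None
) -> PowerSpectrum:
    """Welch PSD of a single pixel's intensity time series."""
    if params is None:
        params = WelchParams(segment_length=min(256, len(series)))
    params = params.resolved(len(series))
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    if len(series) != meta.n_frames:
        raise ValueError(
            f"series length {len(series)} does not match meta.n_frames "
            f"{meta.n_frames}"
        )
    freqs, psd = _welch_nd(series, meta.frame_rate, params)
    # numerical negatives from cancellation are clamped
    return PowerSpectrum(freqs=freqs, psd=np.maximum(psd, 0.0))


def _moments(freqs: np.ndarray, psd: np.ndarray, axis: int = 0):
    """PSD-weighted first moment and central second moment along ``axis``.

    Degenerate pixels (zero total power) get fmean = fstd = 0.
    """
    total = psd.sum(axis=axis)
    shape = [1] * psd.ndim
    shape[axis] = -1
    f = freqs.reshape(shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (psd * f).sum(axis=axis) / total
        m2 = (psd * f * f).sum(axis=axis) / total
    m1 = np.where(total > 0, m1, 0.0)
    m2 = np.where(total > 0, m2, 0.0)
    var = m2 - m1 * m1
    if np.any(var < -1e-9 * np.maximum(m2, 1.0)):
        raise FloatingPointError("negative spectral variance beyond tolerance")
    return m1, np.sqrt(np.maximum(var, 0.0))


def mean_frequency(spectrum: PowerSpectrum) -> float:
    """PSD-weighted centroid frequency in Hz; 0 for a zero-power spectrum."""
    m1, _ = _moments(spectrum.freqs, spectrum.psd)
    return float(m1)


def frequency_std(spectrum: PowerSpectrum) -> float:
    """PSD-weighted frequency standard deviation (bandwidth) in Hz."""
    _, s = _moments(spectrum.freqs, spectrum.psd)
    return float(s)


def intensity_std(stack: TimeSeriesStack) -> np.ndarray:
    """Per-pixel temporal standard deviation (population 1/N form)."""
    return stack.values.std(axis=0, ddof=0)


def smooth_map(raster: np.ndarray, sigma: float = 3.0, kernel: int = 3) -> np.ndarray:
    """Gaussian-filter a map with an explicitly truncated kernel.

    A sigma of 3 truncated to a 3x3 support is a heavily clipped, nearly
    uniform 3x3 average; borders are replicate-padded.
    """
    radius = (kernel - 1) // 2
    return ndimage.gaussian_filter(
        raster, sigma=sigma, truncate=radius / sigma, mode="nearest"
    )


def _chunk_slices(n: int, n_chunks_axis: int) -> list[slice]:
    edges = np.linspace(0, n, n_chunks_axis + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def compute_dynamics_maps(
    stack: TimeSeriesStack,
    params: WelchParams | None = None,
    *,
    normalize: bool = True,
    smooth: bool = True,
    smooth_sigma: float = 3.0,
    smooth_kernel: int = 3,
    n_chunks: int = 1,
) -> DynamicsMaps:
    """Compute the fmean / fstd / STD maps for one cross-section.

    ``n_chunks`` in {1, 4, 9} tiles the image spatially for piecewise
    computation (the memory/parallelism contract of the quartered-cube
    scheme); per-pixel spectra are independent, so any tiling yields
    identical maps.  Smoothing (when on) applies to the fmean raster
    only, after per-pixel computation.
    """
    if n_chunks not in (1, 4, 9):
        raise ValueError(f"n_chunks must be 1, 4 or 9, got {n_chunks}")
    if params is None:
        params = WelchParams(segment_length=min(256, stack.n_frames))
    params = params.resolved(stack.n_frames)
    if normalize:
        stack = normalize_frames(stack)
    values = stack.values
    _, nz, nx = values.shape
    fmean = np.empty((nz, nx))
    fstd = np.empty((nz, nx))
    per_axis = int(round(n_chunks**0.5))
    for zs in _chunk_slices(nz, per_axis):
        for xs in _chunk_slices(nx, per_axis):
            freqs, psd = _welch_nd(
                values[:, zs, xs], stack.meta.frame_rate, params
            )
            m1, s = _moments(freqs, np.maximum(psd, 0.0), axis=0)
            fmean[zs, xs] = m1
            fstd[zs, xs] = s
    if smooth:
        fmean = smooth_map(fmean, sigma=smooth_sigma, kernel=smooth_kernel)
    return DynamicsMaps(
        fmean=fmean,
        fstd=fstd,
        std=intensity_std(stack),
        params=params,
        frame_rate=stack.meta.frame_rate,
        smoothed=smooth,
    )
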