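"""Stack I/O and acquisition-metadata arithmetic.

Dynamic OCT acquires a time series of B-scans (cross-sectional intensity
images) at a fixed frame rate.  This module reads/writes such stacks as
multi-page TIFFs, carries the acquisition metadata (frame rate, pixel
pitch, geometry) alongside the raster, and provides the small pieces of
sampling arithmetic that fix the measurable frequency range and the
physical dimensions of the images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "TimeSeriesStack",
    "read_stack",
    "write_stack",
    "read_volume",
    "write_volume",
    "nyquist_limit",
    "required_sampling_rate",
    "tissue_axial_resolution",
    "field_of_view",
    "load_config",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of a repeated-B-scan time series.

    Parameters
    ----------
    frame_rate : float
        B-scan repetition rate in Hz.
    n_frames : int
        Number of repeated frames per cross-section.
    pixel_axial, pixel_lateral : float
        Pixel pitch in micrometres along depth (z) and lateral (x).
    n_axial, n_lateral : int
        Image height (pixels per A-scan, possibly cropped) and width
        (A-scans per B-scan).
    refractive_index : float
        Bulk refractive index of the sample, used to convert the
        in-air axial resolution to in-tissue values.
    y_spacing : float
        Spacing between adjacent B-scan planes in micrometres, for
        volumetric (per-y) datasets.
    """

    frame_rate: float = 56.0
    n_frames: int = 512
    pixel_axial: float = 2.53
    pixel_lateral: float = 2.53
    n_axial: int = 660
    n_lateral: int = 660
    refractive_index: float = 1.38
    y_spacing: float = 2.53

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.pixel_axial <= 0 or self.pixel_lateral <= 0:
            raise ValueError("pixel sizes must be > 0")
        if self.refractive_index < 1:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )

    @property
    def frame_interval(self) -> float:
        """Time between frames in seconds."""
        return 1.0 / self.frame_rate


@dataclass
class TimeSeriesStack:
    """A 3D intensity raster (time, depth z, lateral x) with metadata.

    ``values[t]`` is the B-scan captured at time ``t / meta.frame_rate``.
    """

    values: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"stack must be 3D (time, z, x), got shape {self.values.shape}"
            )
        if self.values.shape[0] != self.meta.n_frames:
            raise ValueError(
                f"time axis length {self.values.shape[0]} does not match "
                f"meta.n_frames {self.meta.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "TimeSeriesStack":
        return TimeSeriesStack(values=values, meta=self.meta)


# ---------------------------------------------------------------------------
# metadata arithmetic
# ---------------------------------------------------------------------------

def nyquist_limit(meta: AcquisitionMeta) -> float:
    """Highest motion frequency measurable without aliasing, in Hz.

    Half the B-scan frame rate (Shannon); a 56 fps acquisition can
    resolve fluctuations between 0 and 28 Hz.
    """
    return meta.frame_rate / 2.0


def required_sampling_rate(max_motion_freq: float) -> float:
    """Minimum frame rate (Hz) needed to resolve motion up to a given frequency.

    The Shannon bound: twice the highest motion frequency of interest.
    """
    if max_motion_freq <= 0:
        raise ValueError(f"max_motion_freq must be > 0, got {max_motion_freq}")
    return 2.0 * max_motion_freq


def tissue_axial_resolution(air_resolution: float, refractive_index: float) -> float:
    """Axial resolution inside the sample in micrometres.

    The in-air coherence length shrinks by the sample's refractive index.
    """
    if air_resolution <= 0 or refractive_index <= 0:
        raise ValueError("air_resolution and refractive_index must be > 0")
    return air_resolution / refractive_index


def field_of_view(meta: AcquisitionMeta) -> tuple[float, float]:
    """(lateral, axial) extent of the B-scan in millimetres."""
    lateral = meta.n_lateral * meta.pixel_lateral / 1000.0
    axial = meta.n_axial * meta.pixel_axial / 1000.0
    return lateral, axial


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    meta: AcquisitionMeta,
    *,
    crop_depth: tuple[int, int] | None = None,
) -> TimeSeriesStack:
    """Read a repeated-B-scan time series from a multi-page TIFF.

    Pages are frames; each page must be a 2D (depth, lateral) image.
    ``crop_depth=(z0, z1)`` crops every frame to rows ``z0:z1`` on
    ingest (e.g. trimming 1024-pixel A-scans to a 660-pixel window);
    ``meta`` must describe the *cropped* geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    if crop_depth is not None:
        z0, z1 = crop_depth
        values = values[:, z0:z1, :]
    expected = (meta.n_frames, meta.n_axial, meta.n_lateral)
    if values.shape != expected:
        raise ValueError(
            f"stack shape mismatch for {path}: expected {expected} "
            f"(frames, depth, lateral), found {values.shape}"
        )
    return TimeSeriesStack(values=np.asarray(values, dtype=np.float64), meta=meta)


def write_stack(path: str | Path, stack: TimeSeriesStack) -> Path:
    """Write a time-series stack as a 32-bit float multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.values.astype(np.float32), photometric="minisblack")
    return path


_MANIFEST_NAME = "volume.yaml"


def write_volume(
    directory: str | Path,
    stacks: list[TimeSeriesStack],
    *,
    labels: np.ndarray | None = None,
) -> Path:
    """Write a volumetric dataset: one multi-page TIFF per y plane plus a manifest.

    Matches the acquisition protocol — one repeated-B-scan series per y
    position — and keeps any single file small.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, stack in enumerate(stacks):
        name = f"y{i:04d}.tif"
        write_stack(directory / name, stack)
        names.append(name)
    meta = stacks[0].meta
    manifest = {
        "stacks": names,
        "y_spacing_um": meta.y_spacing,
        "frame_rate_hz": meta.frame_rate,
        "n_frames": meta.n_frames,
        "pixel_axial_um": meta.pixel_axial,
        "pixel_lateral_um": meta.pixel_lateral,
        "n_axial": meta.n_axial,
        "n_lateral": meta.n_lateral,
        "refractive_index": meta.refractive_index,
    }
    if labels is not None:
        tifffile.imwrite(directory / "labels.tif", labels.astype(np.uint8))
        manifest["labels"] = "labels.tif"
    with open(directory / _MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory


def read_volume(directory: str | Path) -> list[TimeSeriesStack]:
    """Read a volumetric dataset written by :func:`write_volume`."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"volume manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    meta = AcquisitionMeta(
        frame_rate=manifest["frame_rate_hz"],
        n_frames=manifest["n_frames"],
        pixel_axial=manifest["pixel_axial_um"],
        pixel_lateral=manifest["pixel_lateral_um"],
        n_axial=manifest["n_axial"],
        n_lateral=manifest["n_lateral"],
        refractive_index=manifest.get("refractive_index", 1.38),
        y_spacing=manifest["y_spacing_um"],
    )
    return [read_stack(directory / name, meta) for name in manifest["stacks"]]


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML processing config; returns a plain dict.

    Recognised sections: ``acquisition`` (AcquisitionMeta fields),
    ``welch`` (segment_length, overlap, window, detrend), ``smooth``
    (enabled, sigma, kernel), ``segment`` (threshold_hz, rim_width,
    reassign), ``render`` (f_lo, f_hi, hue_max, sat_norm, val_norm).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def meta_from_config(cfg: dict) -> AcquisitionMeta:
    """Build an :class:`AcquisitionMeta` from a config dict's ``acquisition`` section."""
    acq = cfg.get("acquisition", {})
    return AcquisitionMeta(**acq)
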