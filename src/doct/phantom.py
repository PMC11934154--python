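"""Synthetic spheroid phantoms with known per-layer temporal spectra.

No public dynamic-OCT spheroid datasets exist, so the pipeline is
exercised on phantoms: layered ellipsoids whose pixel time series are
drawn from temporal processes with closed-form power spectra.  The
viable shell fluctuates strongly and at low frequency, the necrotic
core weakly and at high frequency — the statistical contrast the
method measures — and an optional bright broadband ring at the outer
boundary emulates the interface-reflection artifact.  Every phantom
carries its ground-truth label raster and the analytic expected
centroid frequency of each layer, so recovery can be checked exactly.

Two temporal processes are offered:

* ``band_tones`` — a sum of equal-amplitude random-phase cosines on
  the DFT grid inside a band [f1, f2]; its PSD is a row of equal
  spikes, so the expected centroid is essentially the band midpoint;
* ``ar1_plus_white`` — a mean-zero AR(1) (Lorentzian PSD concentrated
  at low frequency) plus a flat white floor; more speckle-realistic.

Both may carry an additive white floor; speckle is modelled as a
static per-pixel reflectivity texture multiplying the common layer
dynamics, which cancels in the normalised centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AcquisitionMeta, TimeSeriesStack

__all__ = [
    "LayerProcess",
    "EdgeRing",
    "PhantomSpec",
    "expected_fmean",
    "process_psd",
    "generate_phantom",
    "generate_phantom_volume",
    "growth_series",
    "LABEL_BACKGROUND",
    "LABEL_VIABLE",
    "LABEL_NECROTIC",
    "LABEL_EDGE_RING",
]

LABEL_BACKGROUND = 0
LABEL_VIABLE = 1
LABEL_NECROTIC = 2
LABEL_EDGE_RING = 3


@dataclass(frozen=True)
class LayerProcess:
    """Temporal fluctuation process of one tissue layer.

    ``fluctuation_amplitude`` is the RMS of the in-band fluctuation
    relative to the layer's mean reflectivity; ``white_floor`` is the
    RMS of an additional flat-spectrum component (detection noise /
    broadband motion).  For ``ar1_plus_white``, ``ar_coeff`` is the
    lag-one autoregression coefficient.
    """

    kind: str = "band_tones"
    band: tuple[float, float] = (8.0, 9.5)
    fluctuation_amplitude: float = 0.3
    white_floor: float = 0.0
    ar_coeff: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("band_tones", "ar1_plus_white"):
            raise ValueError(f"unknown process kind {self.kind!r}")
        f1, f2 = self.band
        if not 0.0 <= f1 < f2:
            raise ValueError(f"band must satisfy 0 <= f1 < f2, got {self.band}")
        if self.fluctuation_amplitude < 0 or self.white_floor < 0:
            raise ValueError("amplitudes must be >= 0")
        if not -1.0 < self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in (-1, 1) for stationarity")


@dataclass(frozen=True)
class EdgeRing:
    """Specular interface-reflection artifact at the spheroid boundary."""

    enabled: bool = False
    width: int = 3
    amplitude: float = 0.25  # RMS of broadband fluctuation
    reflectivity: float = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-layer processes and noise of a synthetic spheroid.

    Defaults mirror the acquisition this emulates: 512 frames at
    56 fps, 2.53 um isotropic pixels, a 660x660 cross-section holding
    a 225-um-radius spheroid (450 um diameter) with a necrotic core of
    half that radius, a viable shell fluctuating in 8-9.5 Hz and a
    necrotic core in 11.5-13 Hz.
    """

    shape: tuple[int, ...] = (660, 660)
    center: tuple[float, ...] | None = None  # pixel coords; image centre if None
    outer_radii: tuple[float, ...] = (225.0, 225.0)  # um, per axis
    core_radii: tuple[float, ...] = (112.5, 112.5)  # um, per axis
    pixel_pitch: float = 2.53  # um
    frame_rate: float = 56.0
    n_frames: int = 512
    viable_process: LayerProcess = field(
        default_factory=lambda: LayerProcess(
            kind="band_tones", band=(8.0, 9.5),
            fluctuation_amplitude=0.3, white_floor=0.02,
        )
    )
    necrotic_process: LayerProcess = field(
        default_factory=lambda: LayerProcess(
            kind="band_tones", band=(11.5, 13.0),
            fluctuation_amplitude=0.1, white_floor=0.02,
        )
    )
    viable_reflectivity: float = 1.0
    necrotic_reflectivity: float = 0.8
    background_noise_sd: float = 0.03
    speckle_contrast: float = 0.3  # sd of the static reflectivity texture
    edge_ring: EdgeRing = field(default_factory=EdgeRing)
    seed: int = 0

    def __post_init__(self) -> None:
        ndim = len(self.shape)
        if ndim not in (2, 3):
            raise ValueError("shape must be (n_z, n_x) or (n_y, n_z, n_x)")
        if len(self.outer_radii) != ndim or len(self.core_radii) != ndim:
            raise ValueError("radii must have one entry per axis")
        if any(c > o for c, o in zip(self.core_radii, self.outer_radii)):
            raise ValueError("core radii must not exceed outer radii")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def meta(self) -> AcquisitionMeta:
        nz, nx = self.shape[-2:]
        return AcquisitionMeta(
            frame_rate=self.frame_rate,
            n_frames=self.n_frames,
            pixel_axial=self.pixel_pitch,
            pixel_lateral=self.pixel_pitch,
            n_axial=nz,
            n_lateral=nx,
            y_spacing=self.pixel_pitch,
        )


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def _tone_freqs(process: LayerProcess, frame_rate: float, n_frames: int) -> np.ndarray:
    """DFT-grid frequencies of the band_tones process (on-grid for the series)."""
    df = frame_rate / n_frames
    f1, f2 = process.band
    k1 = int(np.ceil(f1 / df))
    k2 = int(np.floor(f2 / df))
    if k2 < k1:
        raise ValueError(
            f"band {process.band} Hz contains no DFT frequency at resolution "
            f"{df:.4f} Hz ({n_frames} frames @ {frame_rate} Hz)"
        )
    return df * np.arange(k1, k2 + 1)


def process_psd(
    process: LayerProcess,
    frame_rate: float,
    grid: np.ndarray,
    n_frames: int = 512,
) -> np.ndarray:
    """Closed-form one-sided power distribution of a process on a frequency grid.

    Returned values are per-bin powers (not densities); only relative
    weights matter for centroid computation.  Tone lines are assigned
    to their nearest grid bin.
    """
    grid = np.asarray(grid, dtype=np.float64)
    power = np.zeros_like(grid)
    a2 = process.fluctuation_amplitude**2
    if a2 > 0:
        if process.kind == "band_tones":
            tones = _tone_freqs(process, frame_rate, n_frames)
            per_tone = a2 / len(tones)
            for f in tones:
                power[np.argmin(np.abs(grid - f))] += per_tone
        else:  # ar1_plus_white: Lorentzian, total power = amplitude^2
            a = process.ar_coeff
            dt = 1.0 / frame_rate
            dens = 1.0 / np.abs(1.0 - a * np.exp(-2j * np.pi * grid * dt)) ** 2
            power += a2 * dens / dens.sum()
    if process.white_floor > 0:
        power += process.white_floor**2 / len(grid)
    return power


def expected_fmean(
    process: LayerProcess,
    frame_rate: float,
    grid: np.ndarray,
    n_frames: int = 512,
) -> float:
    """Analytic centroid frequency of a layer process on a given grid."""
    power = process_psd(process, frame_rate, grid, n_frames=n_frames)
    total = power.sum()
    if total == 0:
        return 0.0
    return float((power * np.asarray(grid)).sum() / total)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _ellipsoid_labels(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label raster for the (2D or 3D) geometry."""
    ndim = len(spec.shape)
    center = spec.center
    if center is None:
        center = tuple((n - 1) / 2.0 for n in spec.shape)
    coords = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in spec.shape], indexing="ij"
    )
    outer = np.zeros(spec.shape)
    for ax in range(ndim):
        d_um = (coords[ax] - center[ax]) * spec.pixel_pitch
        outer += (d_um / spec.outer_radii[ax]) ** 2
    labels = np.zeros(spec.shape, dtype=np.uint8)
    inside = outer <= 1.0
    labels[inside] = LABEL_VIABLE
    if all(r > 0 for r in spec.core_radii):
        core = np.zeros(spec.shape)
        for ax in range(ndim):
            d_um = (coords[ax] - center[ax]) * spec.pixel_pitch
            core += (d_um / spec.core_radii[ax]) ** 2
        labels[core <= 1.0] = LABEL_NECROTIC
    if spec.edge_ring.enabled:
        # ring: inside pixels within `width` pixels of the outer surface,
        # measured on the normalised ellipse coordinate
        r_out = np.sqrt(outer)
        mean_radius_px = np.mean(spec.outer_radii) / spec.pixel_pitch
        ring = inside & (r_out >= 1.0 - spec.edge_ring.width / mean_radius_px)
        labels[ring] = LABEL_EDGE_RING
    return labels


def _fluctuation(
    process: LayerProcess, n_pixels: int, n_frames: int, frame_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_frames, n_pixels) zero-mean fluctuation realisations of a process."""
    t = np.arange(n_frames) / frame_rate
    out = np.zeros((n_frames, n_pixels))
    if process.fluctuation_amplitude > 0:
        if process.kind == "band_tones":
            tones = _tone_freqs(process, frame_rate, n_frames)
            # per-tone RMS amplitude so that total variance = amplitude^2
            amp = process.fluctuation_amplitude * np.sqrt(2.0 / len(tones))
            phases = rng.uniform(0, 2 * np.pi, size=(len(tones), n_pixels))
            for f, ph in zip(tones, phases):
                out += amp * np.cos(2 * np.pi * f * t[:, None] + ph[None, :])
        else:
            a = process.ar_coeff
            innov_sd = process.fluctuation_amplitude * np.sqrt(1 - a * a)
            e = rng.normal(0.0, innov_sd, size=(n_frames, n_pixels))
            out[0] = rng.normal(
                0.0, process.fluctuation_amplitude, size=n_pixels
            )
            for i in range(1, n_frames):
                out[i] = a * out[i - 1] + e[i]
    if process.white_floor > 0:
        out += rng.normal(0.0, process.white_floor, size=(n_frames, n_pixels))
    return out


def _edge_process(spec: PhantomSpec) -> LayerProcess:
    """Broadband process of the specular edge ring (flat over 0-Nyquist)."""
    return LayerProcess(
        kind="band_tones",
        band=(0.0, spec.frame_rate / 2.0),
        fluctuation_amplitude=0.0,
        white_floor=spec.edge_ring.amplitude,
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[TimeSeriesStack, np.ndarray, dict[str, float]]:
    """Generate one cross-sectional phantom.

    Returns ``(stack, labels, expected)`` where ``labels`` is the
    ground-truth raster (0 background, 1 viable, 2 necrotic, 3 edge
    ring) and ``expected`` maps layer name to the analytic centroid
    frequency on the full-series DFT grid.  Identical specs (same
    seed) give bitwise-identical stacks.
    """
    if len(spec.shape) != 2:
        raise ValueError("generate_phantom expects a 2D spec; see generate_phantom_volume")
    labels = _ellipsoid_labels(spec)
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    # background: magnitude noise floor (backscatter intensity is nonnegative)
    values = np.abs(
        rng.normal(0.0, spec.background_noise_sd, size=(n_frames,) + spec.shape)
    )
    layer_defs = [
        (LABEL_VIABLE, spec.viable_process, spec.viable_reflectivity),
        (LABEL_NECROTIC, spec.necrotic_process, spec.necrotic_reflectivity),
    ]
    if spec.edge_ring.enabled:
        layer_defs.append(
            (LABEL_EDGE_RING, _edge_process(spec),
             spec.edge_ring.reflectivity * spec.viable_reflectivity)
        )
    for label, process, reflectivity in layer_defs:
        idx = np.flatnonzero(labels.ravel() == label)
        if idx.size == 0:
            continue
        # static speckle texture: gamma with mean 1, sd = speckle_contrast
        if spec.speckle_contrast > 0:
            k = 1.0 / spec.speckle_contrast**2
            texture = rng.gamma(k, 1.0 / k, size=idx.size)
        else:
            texture = np.ones(idx.size)
        fluct = _fluctuation(process, idx.size, n_frames, spec.frame_rate, rng)
        series = reflectivity * texture[None, :] * (1.0 + fluct)
        flat = values.reshape(n_frames, -1)
        flat[:, idx] = series
    grid = np.fft.rfftfreq(n_frames, d=1.0 / spec.frame_rate)
    expected = {
        "viable": expected_fmean(
            spec.viable_process, spec.frame_rate, grid, n_frames=n_frames
        ),
        "necrotic": expected_fmean(
            spec.necrotic_process, spec.frame_rate, grid, n_frames=n_frames
        ),
    }
    if spec.edge_ring.enabled:
        expected["edge_ring"] = expected_fmean(
            _edge_process(spec), spec.frame_rate, grid, n_frames=n_frames
        )
    stack = TimeSeriesStack(values=values, meta=spec.meta)
    return stack, labels, expected


def _derive_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([seed, *keys])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_phantom_volume(
    spec: PhantomSpec,
) -> tuple[list[TimeSeriesStack], np.ndarray, dict[str, float]]:
    """Generate a 3D phantom as per-y cross-sectional stacks.

    The spec's shape is (n_y, n_z, n_x); each y plane is generated as
    a 2D phantom whose in-plane radii follow the ellipsoid's
    intersection with that plane, with a per-plane derived seed.
    Returns (stacks, labels3d, expected).
    """
    if len(spec.shape) != 3:
        raise ValueError("generate_phantom_volume expects a 3D spec")
    n_y, n_z, n_x = spec.shape
    center = spec.center
    if center is None:
        center = tuple((n - 1) / 2.0 for n in spec.shape)
    labels3d = _ellipsoid_labels(spec)
    stacks: list[TimeSeriesStack] = []
    expected: dict[str, float] = {}
    for iy in range(n_y):
        dy_um = (iy - center[0]) * spec.pixel_pitch
        def slice_radii(radii: tuple[float, ...]) -> tuple[float, float]:
            ry, rz, rx = radii
            if ry <= 0 or abs(dy_um) >= ry:
                return (0.0, 0.0)
            scale = np.sqrt(1.0 - (dy_um / ry) ** 2)
            return (rz * scale, rx * scale)
        outer2d = slice_radii(spec.outer_radii)
        core2d = slice_radii(spec.core_radii)
        spec2d = replace(
            spec,
            shape=(n_z, n_x),
            center=(center[1], center[2]),
            outer_radii=outer2d if outer2d != (0.0, 0.0) else (1e-9, 1e-9),
            core_radii=core2d,
            seed=_derive_seed(spec.seed, iy),
        )
        stack, _, expected = generate_phantom(spec2d)
        stacks.append(stack)
    return stacks, labels3d, expected


def growth_series(
    spec: PhantomSpec,
    days: list[int],
    core_radius_schedule: list[float],
) -> list[tuple[int, TimeSeriesStack, np.ndarray, dict[str, float]]]:
    """One phantom per culture day with a (non-decreasing) growing core.

    ``core_radius_schedule`` gives the isotropic core radius in um for
    each day; seeds derive deterministically from (spec.seed, day).
    Returns a list of (day, stack, labels, expected) tuples.
    """
    if len(days) != len(core_radius_schedule):
        raise ValueError("days and core_radius_schedule must have equal length")
    if any(b < a for a, b in zip(core_radius_schedule, core_radius_schedule[1:])):
        raise ValueError("core radii must be non-decreasing over days")
    out = []
    for day, r_core in zip(days, core_radius_schedule):
        day_spec = replace(
            spec,
            core_radii=tuple(r_core for _ in spec.shape),
            seed=_derive_seed(spec.seed, int(day)),
        )
        stack, labels, expected = generate_phantom(day_spec)
        out.append((day, stack, labels, expected))
    return out
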