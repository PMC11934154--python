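"""Cross-section, depth-profile and longitudinal summaries.

The scalar readouts of the method: the average fmean over a mask (the
per-cross-section viability indicator), depth profiles of class-wise
average fmean through a volume (necrosis peaks at the spheroid
centre), and tidy longitudinal tables of central-slice fmean and
viability over culture days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AcquisitionMeta

__all__ = [
    "LongitudinalRecord",
    "mean_fmean_over_mask",
    "depth_profile",
    "longitudinal_table",
]


@dataclass(frozen=True)
class LongitudinalRecord:
    """One (sample, day) observation of central-slice activity."""

    day: int
    sample_id: str
    mean_fmean_center: float
    viability: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be non-negative")


def mean_fmean_over_mask(fmean_map: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of fmean over the mask pixels (sum / pixel count)."""
    if fmean_map.shape != mask.shape:
        raise ValueError("map and mask must share one shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: mean fmean undefined")
    return float(fmean_map[mask].sum() / n)


def depth_profile(
    volume_maps,
    volume_masks,
    meta: AcquisitionMeta,
) -> pd.DataFrame:
    """Class-wise average fmean per cross-section through a volume.

    ``volume_maps`` and ``volume_masks`` are aligned sequences of
    DynamicsMaps and SegmentationResult, one per y plane at
    ``meta.y_spacing`` micrometres.  Depth 0 is the first plane whose
    spheroid mask is non-empty.  Rows exist only where the class mask
    is non-empty; columns: depth_um, slice_index, class
    (total/viable/necrotic), mean_fmean_hz, n_pixels.
    """
    if len(volume_maps) != len(volume_masks):
        raise ValueError(
            f"got {len(volume_maps)} maps but {len(volume_masks)} masks"
        )
    first = None
    for i, seg in enumerate(volume_masks):
        if seg.spheroid_mask.any():
            first = i
            break
    if first is None:
        raise ValueError("no slice contains a spheroid")
    rows = []
    for i, (maps, seg) in enumerate(zip(volume_maps, volume_masks)):
        if i < first:
            continue
        depth = (i - first) * meta.y_spacing
        for cls, mask in (
            ("total", seg.spheroid_mask),
            ("viable", seg.viable_mask),
            ("necrotic", seg.necrotic_mask),
        ):
            n = int(mask.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "depth_um": depth,
                    "slice_index": i,
                    "class": cls,
                    "mean_fmean_hz": mean_fmean_over_mask(maps.fmean, mask),
                    "n_pixels": n,
                }
            )
    return pd.DataFrame(rows)


def longitudinal_table(records) -> pd.DataFrame:
    """Tidy per-sample time series, sorted by sample then day.

    Duplicate (sample, day) pairs are an error: each monitoring day
    contributes one central-slice measurement per spheroid.
    """
    rows = [
        {
            "sample_id": r.sample_id,
            "day": r.day,
            "mean_fmean_hz": r.mean_fmean_center,
            "viability": r.viability,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "day", "mean_fmean_hz", "viability"])
    if df.duplicated(subset=["sample_id", "day"]).any():
        dup = df[df.duplicated(subset=["sample_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate record for sample {dup['sample_id']!r} day {dup['day']}"
        )
    return df.sort_values(["sample_id", "day"]).reset_index(drop=True)


def profile_confidence_band(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- 1.96 SE band across replicate depth profiles.

    Replicates are matched on (depth_um, class); returns columns
    depth_um, class, mean_fmean_hz, ci_lo, ci_hi, n_replicates.
    """
    cat = pd.concat(profiles, ignore_index=True)
    g = cat.groupby(["depth_um", "class"])["mean_fmean_hz"]
    out = g.agg(mean_fmean_hz="mean", sd="std", n_replicates="count").reset_index()
    se = out["sd"] / np.sqrt(out["n_replicates"])
    out["ci_lo"] = out["mean_fmean_hz"] - 1.96 * se
    out["ci_hi"] = out["mean_fmean_hz"] + 1.96 * se
    return out.drop(columns="sd")
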