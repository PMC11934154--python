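"""Spheroid masking, viability splitting and edge-artifact correction.

A spheroid cross-section is segmented in three steps: (1) an intensity
threshold on a reference raster (temporal-mean intensity or the STD
map) isolates the spheroid from the surrounding medium; (2) the fmean
threshold — the midpoint between the viable band's upper limit and the
necrotic band's lower limit, 10.5 Hz by default — splits the spheroid
into viable (fmean below threshold) and necrotic (at/above) regions;
(3) a rim rule reclassifies the spurious "necrotic" ring produced by
the refractive-index mismatch at the spheroid/medium interface:
necrotic components that touch the spheroid boundary and are confined
to a thin rim are edge artifacts, not dead tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationResult",
    "spheroid_mask",
    "segmentation_threshold",
    "split_by_viability",
    "remove_edge_artifact",
    "viability",
    "segment_cross_section",
    "DEFAULT_THRESHOLD_HZ",
]

DEFAULT_THRESHOLD_HZ = 10.5

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for 2D blobs


@dataclass
class SegmentationResult:
    """Masks and viability statistic for one cross-section.

    ``viable``, ``necrotic`` and ``edge_artifact`` are disjoint subsets
    of ``spheroid``; ``viability`` is |viable| / |spheroid|.
    """

    spheroid_mask: np.ndarray
    viable_mask: np.ndarray
    necrotic_mask: np.ndarray
    edge_artifact_mask: np.ndarray
    threshold: float
    viability: float

    def __post_init__(self) -> None:
        sph = self.spheroid_mask
        for m in (self.viable_mask, self.necrotic_mask, self.edge_artifact_mask):
            if m.shape != sph.shape:
                raise ValueError("all masks must share one shape")
            if np.any(m & ~sph):
                raise ValueError("class masks must be subsets of the spheroid mask")
        if np.any(self.viable_mask & self.necrotic_mask):
            raise ValueError("viable and necrotic masks must be disjoint")

    def labeled(self) -> np.ndarray:
        """Label raster: 0 background, 1 viable, 2 necrotic, 3 edge artifact."""
        out = np.zeros(self.spheroid_mask.shape, dtype=np.uint8)
        out[self.viable_mask] = 1
        out[self.necrotic_mask] = 2
        out[self.edge_artifact_mask] = 3
        return out


def spheroid_mask(
    reference_image: np.ndarray,
    strategy: str = "otsu",
    *,
    threshold: float | None = None,
    fill_holes: bool = True,
    min_area: int = 10,
    min_contrast: float = 1.5,
) -> np.ndarray:
    """Binary spheroid mask from a reference raster.

    ``strategy`` is ``"otsu"`` (automatic) or ``"absolute"`` (requires
    ``threshold``).  Keeps the largest above-threshold 8-connected
    component at or above ``min_area`` pixels; holes filled on request.
    ``min_contrast`` guards against images with no spheroid at all:
    Otsu always splits something, so the mean intensity inside the mask
    must exceed ``min_contrast`` times the mean outside (a near-uniform
    noise plane fails this and raises).
    """
    if strategy == "otsu":
        thr = threshold_otsu(reference_image)
    elif strategy == "absolute":
        if threshold is None:
            raise ValueError("absolute strategy requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    binary = reference_image > thr
    labels, n = ndimage.label(binary, structure=_STRUCT_8)
    if n == 0:
        raise ValueError("no spheroid found: empty mask after thresholding")
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise ValueError(
            f"no spheroid found: largest component has {int(sizes[best - 1])} "
            f"pixels, below min_area {min_area}"
        )
    mask = labels == best
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    outside = ~mask
    if strategy == "otsu" and outside.any() and min_contrast > 1.0:
        bg_mean = float(reference_image[outside].mean())
        fg_mean = float(reference_image[mask].mean())
        if bg_mean > 0 and fg_mean < min_contrast * bg_mean:
            raise ValueError(
                "no spheroid found: foreground/background contrast "
                f"{fg_mean / bg_mean:.2f} below {min_contrast}"
            )
    return mask


def segmentation_threshold(viable_upper: float, necrotic_lower: float) -> float:
    """Viability threshold in Hz: midpoint of the gap between the bands.

    With the viable band topping out at 9.5 Hz and the necrotic band
    starting at 11.5 Hz the threshold is 10.5 Hz.
    """
    if not viable_upper < necrotic_lower:
        raise ValueError(
            f"viable_upper ({viable_upper}) must be below necrotic_lower "
            f"({necrotic_lower})"
        )
    return (viable_upper + necrotic_lower) / 2.0


def split_by_viability(
    fmean_map: np.ndarray, spheroid: np.ndarray, threshold: float = DEFAULT_THRESHOLD_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Split the spheroid into (viable, necrotic) by the fmean threshold.

    Ties at exactly the threshold go to necrotic.
    """
    if fmean_map.shape != spheroid.shape:
        raise ValueError("fmean map and spheroid mask must share one shape")
    viable = spheroid & (fmean_map < threshold)
    necrotic = spheroid & (fmean_map >= threshold)
    return viable, necrotic


def _boundary(spheroid: np.ndarray) -> np.ndarray:
    """Pixels of the spheroid adjacent to background (its outer boundary)."""
    return spheroid & ~ndimage.binary_erosion(
        spheroid, structure=_STRUCT_8, border_value=0
    )


def remove_edge_artifact(
    necrotic_mask: np.ndarray,
    spheroid: np.ndarray,
    rim_width: int = 5,
    reassign: str = "viable",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reclassify boundary-hugging necrotic components as edge artifacts.

    A necrotic 8-connected component is an interface-reflection
    artifact when it touches the spheroid boundary and lies entirely
    within ``rim_width`` pixels (Euclidean distance) of that boundary.
    Interior necrotic components are untouched.

    Returns ``(necrotic, edge_artifact, viable_additions)`` where
    ``viable_additions`` is the set of reclassified pixels to merge
    into the viable mask when ``reassign == "viable"`` (empty for
    ``"exclude"``).
    """
    if reassign not in ("viable", "exclude"):
        raise ValueError(f"reassign must be 'viable' or 'exclude', got {reassign!r}")
    boundary = _boundary(spheroid)
    # distance of every pixel to the nearest boundary pixel
    dist = ndimage.distance_transform_edt(~boundary)
    labels, n = ndimage.label(necrotic_mask, structure=_STRUCT_8)
    edge = np.zeros_like(necrotic_mask)
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        if not np.any(comp_mask & boundary):
            continue
        if np.max(dist[comp_mask]) <= rim_width:
            edge |= comp_mask
    necrotic = necrotic_mask & ~edge
    additions = edge.copy() if reassign == "viable" else np.zeros_like(edge)
    return necrotic, edge, additions


def viability(result: SegmentationResult) -> float:
    """Fraction of spheroid pixels classified viable."""
    n_sph = int(result.spheroid_mask.sum())
    if n_sph == 0:
        raise ValueError("empty spheroid mask: viability undefined")
    return float(result.viable_mask.sum() / n_sph)


def segment_cross_section(
    fmean_map: np.ndarray,
    reference_image: np.ndarray,
    *,
    threshold: float = DEFAULT_THRESHOLD_HZ,
    strategy: str = "otsu",
    abs_threshold: float | None = None,
    min_area: int = 10,
    rim_width: int = 5,
    reassign: str = "viable",
    correct_edge: bool = True,
) -> SegmentationResult:
    """Full segmentation of one cross-section.

    Masks the spheroid on ``reference_image``, splits by the fmean
    threshold, and (by default) applies the edge-artifact rim
    correction before computing the viability ratio.
    """
    sph = spheroid_mask(
        reference_image, strategy, threshold=abs_threshold, min_area=min_area
    )
    viable, necrotic = split_by_viability(fmean_map, sph, threshold)
    if correct_edge:
        necrotic, edge, additions = remove_edge_artifact(
            necrotic, sph, rim_width=rim_width, reassign=reassign
        )
        viable = viable | additions
    else:
        edge = np.zeros_like(sph)
    result = SegmentationResult(
        spheroid_mask=sph,
        viable_mask=viable,
        necrotic_mask=necrotic,
        edge_artifact_mask=edge,
        threshold=threshold,
        viability=0.0,
    )
    result.viability = viability(result)
    return result
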