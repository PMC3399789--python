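"""Morphological therapy-response endpoints from ROI label masks.

Endpoints: total tumor volume (voxel count × in-plane area × slice extent,
where the slice extent is thickness + gap), its percent change, the relative
viable rim (100 × maximal in-plane rim thickness / maximal tumor diameter, %)
and the relative necrosis volume (100 × necrotic-core volume / tumor
volume, %).

Diameters follow the caliper (edge-to-edge) convention: the maximal pairwise
in-plane distance between voxel centers within a slice plus one in-plane
voxel extent, maximized over slices. Rim thickness is measured on the slice
with the largest tumor diameter that contains the necrotic core — measuring
it off-center, where the core vanishes, would degenerate to the tumor radius.
When there is no core at all the rim is the whole tumor and the relative rim
is 100% by convention; an empty rim gives 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import ConvexHull, QhullError

from .adc import percent_change
from .io import AcquisitionMeta, RoiMaskSet, ValidationError

__all__ = [
    "MorphometryRecord",
    "tumor_volume",
    "volume_change_percent",
    "max_in_plane_diameter",
    "relative_viable_rim",
    "relative_necrosis_volume",
    "morphometry_record",
]


@dataclass
class MorphometryRecord:
    """Morphological summary of one examination."""

    tumor_volume: float  # mm^3
    max_tumor_diameter: float  # mm
    max_rim_thickness: float  # mm
    rim_percent: float  # %
    necrosis_percent: float  # %


def tumor_volume(masks: RoiMaskSet, meta: AcquisitionMeta) -> float:
    """Total tumor volume: voxel count × in-plane area × (thickness + gap)."""
    mask = masks.region_mask("tumor")
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("tumor region is absent or empty")
    return n * meta.voxel_volume


def volume_change_percent(pre_volume: float, post_volume: float) -> float:
    """Tumor volume change, %: delegates to the shared percent-change contract."""
    return percent_change(pre_volume, post_volume)


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise distance among 2D points (convex hull shortcut)."""
    if points.shape[0] == 1:
        return 0.0
    if points.shape[0] > 40:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) clouds fall back to brute force
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def max_in_plane_diameter(
    masks: RoiMaskSet, region: str, meta: AcquisitionMeta
) -> float:
    """Maximal in-plane Feret diameter of a region, edge-to-edge, over slices.

    The edge-to-edge convention adds one in-plane voxel extent (the larger
    spacing) to the center-to-center distance; a single voxel therefore has
    the extent of one voxel.
    """
    mask = masks.region_mask(region)
    if not mask.any():
        raise ValidationError(f"region {region!r} is absent or empty")
    sx, sy = meta.in_plane_spacing
    extent = max(sx, sy)
    best = 0.0
    for z in range(mask.shape[2]):
        idx = np.argwhere(mask[:, :, z])
        if idx.size == 0:
            continue
        pts = idx.astype(float) * np.array([sx, sy])
        best = max(best, _max_pairwise_distance(pts))
    return best + extent


def _rim_thickness_mm(masks: RoiMaskSet, meta: AcquisitionMeta) -> float:
    """Maximal in-plane radial rim thickness on the reference slice.

    The reference slice is the one with the largest tumor diameter among
    slices containing both rim and core; thickness is the largest in-plane
    distance from a rim voxel to the necrotic core.
    """
    rim = masks.region_mask("viable_rim")
    core = masks.region_mask("necrotic_core")
    sx, sy = meta.in_plane_spacing
    tumor = masks.region_mask("tumor")

    candidates = [
        z
        for z in range(rim.shape[2])
        if rim[:, :, z].any() and core[:, :, z].any()
    ]
    if not candidates:
        return float("nan")  # no-core limit, handled by the caller

    def slice_diameter(z: int) -> float:
        pts = np.argwhere(tumor[:, :, z]).astype(float) * np.array([sx, sy])
        return _max_pairwise_distance(pts)

    z_ref = max(candidates, key=slice_diameter)
    dist_to_core = distance_transform_edt(~core[:, :, z_ref], sampling=(sx, sy))
    return float(dist_to_core[rim[:, :, z_ref]].max())


def relative_viable_rim(masks: RoiMaskSet, meta: AcquisitionMeta) -> float:
    """Relative viable rim: 100 × maximal rim thickness / maximal tumor diameter.

    Returns 100% when the tumor has no necrotic core (the rim is the whole
    tumor) and 0% for an empty rim.
    """
    tumor = masks.region_mask("tumor")
    if not tumor.any():
        raise ValidationError("tumor region is absent or empty")
    rim = masks.region_mask("viable_rim")
    if not rim.any():
        return 0.0
    thickness = _rim_thickness_mm(masks, meta)
    if not np.isfinite(thickness):
        return 100.0
    diameter = max_in_plane_diameter(masks, "tumor", meta)
    return float(min(100.0, 100.0 * thickness / diameter))


def relative_necrosis_volume(masks: RoiMaskSet, meta: AcquisitionMeta) -> float:
    """Relative necrosis volume: 100 × core volume / tumor volume (%).

    Pure voxel counting — volumes are additive over the rim/core partition.
    """
    tumor = masks.region_mask("tumor")
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValidationError("tumor region is absent or empty")
    n_core = int(masks.region_mask("necrotic_core").sum())
    return 100.0 * n_core / n_tumor


def morphometry_record(masks: RoiMaskSet, meta: AcquisitionMeta) -> MorphometryRecord:
    """All morphological endpoints of one examination."""
    thickness = _rim_thickness_mm(masks, meta)
    return MorphometryRecord(
        tumor_volume=tumor_volume(masks, meta),
        max_tumor_diameter=max_in_plane_diameter(masks, "tumor", meta),
        max_rim_thickness=thickness,
        rim_percent=relative_viable_rim(masks, meta),
        necrosis_percent=relative_necrosis_volume(masks, meta),
    )
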