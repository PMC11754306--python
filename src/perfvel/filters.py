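"""Censoring of spurious artery detections.

Four automatic filters plus manual censoring, applied in a fixed order:
ROI erosion (before detection), shape filter (in-plane vessels), duplicate
suppression, ghosting exclusion zones, then manual decisions. Each filter
only moves a cluster's status away from ``candidate``; the included set is
always a subset of the detected candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .detect import VesselCluster
from .io import EmptyRoiError, RoiMask

__all__ = [
    "ExclusionZone",
    "erode_roi",
    "axes_ratio",
    "shape_filter",
    "deduplicate",
    "bright_vessel_zones",
    "ghost_filter",
    "manual_censor",
    "read_censor_decisions",
]

# Variance of a uniform unit pixel: regularizes the second-moment ellipse so
# single voxels and collinear voxel sets get finite, meaningful axes.
_PIXEL_VARIANCE = 1.0 / 12.0

_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross


@dataclass(frozen=True)
class ExclusionZone:
    """Axis-aligned rectangle around a bright in-plane vessel cluster.

    Ghost replicas of bright vessels appear displaced along the
    phase-encode axis, so the zone is the cluster's bounding box dilated
    far along that axis and a little perpendicular to it.
    """

    row_min: int
    row_max: int  # inclusive
    col_min: int
    col_max: int
    source_cluster: int

    def contains(self, row: float, col: float) -> bool:
        return (
            self.row_min <= row <= self.row_max
            and self.col_min <= col <= self.col_max
        )


def erode_roi(roi: RoiMask, n_voxels: int) -> RoiMask:
    """Shrink the ROI edge by ``n_voxels`` single-voxel erosion passes.

    Each pass erodes with a 3x3 cross, removing a one-voxel band; outer-rim
    voxels are the most motion-corrupted, notably in the semioval center.
    """
    if n_voxels < 0:
        raise ValueError("erosion count must be >= 0")
    if n_voxels == 0:
        return RoiMask(roi.mask.copy())
    eroded = ndimage.binary_erosion(
        roi.mask, structure=_CROSS, iterations=n_voxels, border_value=0
    )
    if not eroded.any():
        raise EmptyRoiError(f"ROI eroded to empty after {n_voxels} passes")
    return RoiMask(eroded)


def axes_ratio(cluster: VesselCluster) -> float:
    """Axes ratio of the moment-matched ellipse of the cluster's voxels.

    Eigenvalues of the second central moments of the voxel centers, each
    floored at the unit-pixel variance 1/12, give squared semi-axes; the
    ratio is sqrt(lmax/lmin) >= 1. A single voxel and any rotationally
    symmetric block give 1.0; a 1x6 bar gives sqrt(35) ~ 5.92.
    """
    pts = np.asarray(cluster.voxels, dtype=float)
    if len(pts) == 0:
        raise ValueError("cluster has no voxels")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.maximum(eigvals, _PIXEL_VARIANCE)
    return float(np.sqrt(eigvals[-1] / eigvals[0]))


def shape_filter(
    clusters: list[VesselCluster], axes_ratio_max: float = 2.0
) -> list[VesselCluster]:
    """Exclude elongated (in-plane) clusters: ratio strictly above threshold.

    Velocity in vessels far from perpendicular to the slice is
    underestimated, so round clusters only are kept. The ratio is stored on
    every candidate for reporting either way.
    """
    for c in clusters:
        if c.axes_ratio is None:
            c.axes_ratio = axes_ratio(c)
        if c.status == "candidate" and c.axes_ratio > axes_ratio_max:
            c.status = "excluded_shape"
    return clusters


def deduplicate(
    clusters: list[VesselCluster], min_distance_mm: float = 1.2
) -> list[VesselCluster]:
    """Keep only the highest-velocity detection among near-coincident ones.

    Greedy suppression: candidates sorted by descending |v_mean| (ties by
    centroid row, then col) are accepted in order; a candidate within
    ``min_distance_mm`` (Euclidean, mm) of an accepted one becomes
    ``excluded_duplicate``.
    """
    candidates = [c for c in clusters if c.status == "candidate"]
    for c in candidates:
        if c.v_mean is None:
            raise ValueError("deduplicate requires v_mean on every candidate")
    order = sorted(
        candidates, key=lambda c: (-abs(c.v_mean), c.centroid[0], c.centroid[1])
    )
    accepted: list[VesselCluster] = []
    for c in order:
        pos = np.array(c.centroid_mm)
        if any(
            np.hypot(*(pos - np.array(a.centroid_mm))) < min_distance_mm
            for a in accepted
        ):
            c.status = "excluded_duplicate"
        else:
            accepted.append(c)
    return clusters


def bright_vessel_zones(
    magnitude_mean: np.ndarray,
    ghost_percentile: float = 0.3,
    ghost_min_cluster_voxels: int = 5,
    zone_scale_long: float = 10.0,
    zone_scale_perp: float = 2.0,
    phase_encode_axis: str = "row",
) -> list[ExclusionZone]:
    """Exclusion zones around bright in-plane vessels.

    Voxels in the top ``ghost_percentile`` percent of the temporal-mean
    magnitude (over the full image) form bright clusters; each cluster of at
    least ``ghost_min_cluster_voxels`` voxels yields one zone: its bounding
    box dilated by ``scale * equivalent_diameter`` voxels — ``zone_scale_long``
    along the phase-encode axis (where ghosts replicate) and
    ``zone_scale_perp`` perpendicular — clipped to the image.
    """
    threshold = np.percentile(magnitude_mean, 100.0 - ghost_percentile)
    bright = magnitude_mean > threshold
    cc = measure.label(bright, connectivity=2)
    n_rows, n_cols = magnitude_mean.shape
    zones: list[ExclusionZone] = []
    for region in measure.regionprops(cc):
        if region.num_pixels < ghost_min_cluster_voxels:
            continue
        equiv_diam = float(np.sqrt(4.0 * region.num_pixels / np.pi))
        r0, c0, r1, c1 = region.bbox  # r1/c1 exclusive
        grow_long = int(round(zone_scale_long * equiv_diam))
        grow_perp = int(round(zone_scale_perp * equiv_diam))
        if phase_encode_axis == "row":
            grow_r, grow_c = grow_long, grow_perp
        else:
            grow_r, grow_c = grow_perp, grow_long
        zones.append(
            ExclusionZone(
                row_min=max(0, r0 - grow_r),
                row_max=min(n_rows - 1, r1 - 1 + grow_r),
                col_min=max(0, c0 - grow_c),
                col_max=min(n_cols - 1, c1 - 1 + grow_c),
                source_cluster=int(region.label),
            )
        )
    return zones


def ghost_filter(
    clusters: list[VesselCluster], zones: list[ExclusionZone]
) -> list[VesselCluster]:
    """Exclude candidates whose centroid lies inside any exclusion zone.

    Bright in-plane vessels themselves fall inside their own zone and are
    likewise excluded — they are not perforator detections.
    """
    for c in clusters:
        if c.status != "candidate":
            continue
        if any(z.contains(*c.centroid) for z in zones):
            c.status = "excluded_ghost"
    return clusters


def read_censor_decisions(path) -> dict[int, str]:
    """Parse a decision file: one ``cluster_id,keep|discard`` per line."""
    decisions: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ident, verdict = line.split(",")
            verdict = verdict.strip().lower()
            if verdict not in ("keep", "discard"):
                raise ValueError(f"decision must be keep or discard, got {verdict!r}")
            decisions[int(ident)] = verdict
    return decisions


def manual_censor(
    clusters: list[VesselCluster], decisions: dict[int, str]
) -> list[VesselCluster]:
    """Apply operator keep/discard decisions to every remaining candidate.

    Manual mode overrides the automatic shape and duplicate censoring:
    those statuses are reset to ``candidate`` before decisions apply (the
    ghost filter is not overridden). Every resulting candidate must have a
    decision.
    """
    for c in clusters:
        if c.status in ("excluded_shape", "excluded_duplicate"):
            c.status = "candidate"
    missing = [c.cluster_id for c in clusters if c.status == "candidate" and c.cluster_id not in decisions]
    if missing:
        raise ValueError(f"incomplete censor list: no decision for cluster(s) {missing}")
    for c in clusters:
        if c.status == "candidate" and decisions[c.cluster_id] == "discard":
            c.status = "excluded_manual"
    return clusters
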