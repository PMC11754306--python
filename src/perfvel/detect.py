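"""SNR-threshold voxel classification and candidate-cluster extraction.

A voxel is flagged as part of a perforating artery according to a clustering
profile over the joint (SNR_mag, SNR_v) bins. In the basal ganglia, arteries
flow into the slice, so a voxel must exceed the noise threshold T_n in both
SNR_mag and SNR_v; in the semioval center flow runs the opposite way and a
voxel qualifies when SNR_v falls below -T_n, regardless of SNR_mag. T_n is
the two-sided standard-normal quantile of the chosen significance level
(alpha = 0.05 gives T_n = 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

from .io import CineSeries, RoiMask

__all__ = [
    "ClusterProfile",
    "VesselCluster",
    "noise_threshold",
    "scale_threshold",
    "classify_voxels",
    "extract_clusters",
    "build_clusters",
]

# Cells of the clustering table: (SNR_mag bin, SNR_v bin) with magnitude bins
# "high" (> T_n) / "low" (< T_n) and velocity bins "neg" (< -T_n) /
# "mid" (between) / "pos" (> T_n).
MAG_BINS = ("high", "low")
VEL_BINS = ("neg", "mid", "pos")


@dataclass(frozen=True)
class ClusterProfile:
    """Six-cell boolean rule table mapping SNR bins to artery/not-artery.

    ``sign_flip`` records whether detected velocities are negated for
    reporting, so mean velocities come out positive in both territories.
    """

    location: str
    rules: dict[tuple[str, str], bool]
    sign_flip: bool = False

    def __post_init__(self) -> None:
        expected = {(m, v) for m in MAG_BINS for v in VEL_BINS}
        if set(self.rules) != expected:
            raise ValueError("profile must define all six (SNR_mag, SNR_v) cells")

    @classmethod
    def basal_ganglia(cls) -> "ClusterProfile":
        rules = {(m, v): False for m in MAG_BINS for v in VEL_BINS}
        rules[("high", "pos")] = True
        return cls("basal_ganglia", rules, sign_flip=False)

    @classmethod
    def semioval_center(cls) -> "ClusterProfile":
        rules = {(m, v): False for m in MAG_BINS for v in VEL_BINS}
        rules[("high", "neg")] = True
        rules[("low", "neg")] = True
        return cls("semioval_center", rules, sign_flip=True)

    @classmethod
    def for_location(cls, location: str) -> "ClusterProfile":
        if location == "basal_ganglia":
            return cls.basal_ganglia()
        if location == "semioval_center":
            return cls.semioval_center()
        raise ValueError(f"no preset profile for location {location!r}")

    @classmethod
    def custom(cls, rules: dict[tuple[str, str], bool], sign_flip: bool = False) -> "ClusterProfile":
        return cls("custom", rules, sign_flip=sign_flip)


@dataclass
class VesselCluster:
    """One connected voxel cluster flagged as a candidate artery."""

    cluster_id: int
    voxels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]  # voxel coordinates (row, col)
    centroid_mm: tuple[float, float]
    peak_voxel: tuple[int, int]  # argmax |snr_v_mean| within the cluster
    v_mean: float | None = None  # peak-voxel temporal-mean velocity, cm/s
    mean_snr_v: float | None = None
    axes_ratio: float | None = None
    trace: np.ndarray | None = None
    pi: float | None = None
    status: str = "candidate"

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def noise_threshold(alpha: float) -> float:
    """Two-sided standard-normal quantile: T_n = Phi^-1(1 - alpha/2)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1 - alpha / 2))


def scale_threshold(
    t_n: float,
    n_phases: int,
    temporal_resolution_ms: float,
    tn_scaling_factor: float = 1.0,
) -> float:
    """Effective noise threshold after acquisition-dependent scaling.

    The scaling accounts for the dependence of the SNR estimates on the
    number of reconstructed heart phases and the temporal resolution. No
    universal functional form exists, so the factor is an explicit,
    provenance-logged hook with identity default.
    """
    if n_phases < 2 or temporal_resolution_ms <= 0:
        raise ValueError("n_phases must be >= 2 and temporal resolution positive")
    factor = (
        tn_scaling_factor(n_phases, temporal_resolution_ms)
        if callable(tn_scaling_factor)
        else tn_scaling_factor
    )
    if not factor > 0:
        raise ValueError(f"T_n scaling factor must be positive, got {factor}")
    return t_n * float(factor)


def classify_voxels(
    snr_mag_mean: np.ndarray,
    snr_v_stat: np.ndarray,
    effective_t_n: float,
    profile: ClusterProfile,
    roi: RoiMask,
) -> np.ndarray:
    """Label each ROI voxel artery/not per the profile's rule table.

    ``snr_v_stat`` is the per-voxel temporal reduction of SNR_v (see
    :meth:`perfvel.noise.SNRMaps.detection_statistic`).
    """
    if snr_mag_mean.shape != snr_v_stat.shape or snr_mag_mean.shape != roi.mask.shape:
        raise ValueError("SNR grids and ROI must share one shape")
    mag_high = snr_mag_mean > effective_t_n
    vel_bin = np.where(
        snr_v_stat < -effective_t_n, 0, np.where(snr_v_stat > effective_t_n, 2, 1)
    )
    labels = np.zeros(snr_mag_mean.shape, dtype=bool)
    for (mag_name, vel_name), is_artery in profile.rules.items():
        if not is_artery:
            continue
        cell = (mag_high if mag_name == "high" else ~mag_high) & (
            vel_bin == VEL_BINS.index(vel_name)
        )
        labels |= cell
    return labels & roi.mask


def extract_clusters(
    artery_labels: np.ndarray,
    series: CineSeries,
    snr_v_mean: np.ndarray,
    connectivity: int = 4,
) -> list[VesselCluster]:
    """Connected components of artery voxels as candidate clusters.

    Components use 4- or 8-connectivity; each cluster records its unweighted
    voxel-center centroid (also in mm via anisotropic pixel spacing) and its
    peak voxel (max |snr_v_mean|). Output ordering is deterministic by
    (centroid row, centroid col).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    cc = measure.label(artery_labels, connectivity=1 if connectivity == 4 else 2)
    dy, dx = series.pixel_spacing_mm
    clusters: list[VesselCluster] = []
    for region_label in range(1, cc.max() + 1):
        rows, cols = np.nonzero(cc == region_label)
        centroid = (float(rows.mean()), float(cols.mean()))
        stat = np.abs(snr_v_mean[rows, cols])
        k = int(np.argmax(stat))
        clusters.append(
            VesselCluster(
                cluster_id=-1,  # assigned after sorting
                voxels=np.column_stack([rows, cols]),
                centroid=centroid,
                centroid_mm=(centroid[0] * dy, centroid[1] * dx),
                peak_voxel=(int(rows[k]), int(cols[k])),
            )
        )
    clusters.sort(key=lambda c: c.centroid)
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return clusters


def build_clusters(
    maps,
    series: CineSeries,
    roi: RoiMask,
    effective_t_n: float,
    profile: ClusterProfile | None = None,
    connectivity: int = 4,
    temporal_statistic: str = "mean",
) -> list[VesselCluster]:
    """Classify, extract, and annotate candidate clusters with velocities."""
    profile = profile or ClusterProfile.for_location(series.location)
    stat = maps.detection_statistic(temporal_statistic)
    labels = classify_voxels(maps.snr_mag_mean, stat, effective_t_n, profile, roi)
    clusters = extract_clusters(labels, series, maps.snr_v_mean, connectivity)
    mean_velocity = maps.velocity.mean(axis=2)
    for c in clusters:
        r, col = c.peak_voxel
        c.v_mean = float(mean_velocity[r, col])
        c.mean_snr_v = float(maps.snr_v_mean[r, col])
    return clusters
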