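"""The fixed analysis chain: read → noise → detect → filter → outcomes.

Stage order is fixed: ROI erosion, voxel classification and clustering,
shape filter, duplicate suppression, ghost censoring, then (optionally)
manual censoring; surviving candidates become included vessels, whose
peak-voxel traces feed the pooled outcome measures.
"""

from __future__ import annotations

from pathlib import Path

from . import __version__
from .detect import ClusterProfile, build_clusters, noise_threshold, scale_threshold
from .filters import (
    bright_vessel_zones,
    deduplicate,
    erode_roi,
    ghost_filter,
    manual_censor,
    shape_filter,
)
from .hemodynamics import StudyResult, extract_trace, pooled_outcomes, pulsatility_index
from .io import AnalysisSettings, CineSeries, RoiMask, read_roi_mask, read_series, write_results
from .noise import compute_maps


def analyze(
    series: CineSeries,
    roi: RoiMask,
    settings: AnalysisSettings | None = None,
    profile: ClusterProfile | None = None,
    manual_decisions: dict[int, str] | None = None,
) -> StudyResult:
    """Run the full perforating-artery analysis on one cine series."""
    settings = settings or AnalysisSettings()
    profile = profile or ClusterProfile.for_location(series.location)

    if roi.mask.shape != series.in_plane_shape:
        raise ValueError("ROI shape does not match the series in-plane shape")

    working_roi = roi
    if settings.erosion_active(series.location) and settings.erosion_voxels > 0:
        working_roi = erode_roi(roi, settings.erosion_voxels)

    maps = compute_maps(series, settings.median_kernel_mm, working_roi)

    t_n = noise_threshold(settings.alpha)
    effective_t_n = scale_threshold(
        t_n,
        series.n_phases,
        series.temporal_resolution_ms,
        settings.tn_scaling_factor,
    )

    clusters = build_clusters(
        maps,
        series,
        working_roi,
        effective_t_n,
        profile,
        settings.connectivity,
        settings.temporal_statistic,
    )

    if settings.enable_shape_filter:
        shape_filter(clusters, settings.axes_ratio_max)
    else:  # ratios still reported
        shape_filter(clusters, float("inf"))
    if settings.enable_dedup:
        deduplicate(clusters, settings.dedup_distance_mm)
    if settings.enable_ghost_filter:
        zones = bright_vessel_zones(
            series.magnitude.mean(axis=2),
            settings.ghost_percentile,
            settings.ghost_min_cluster_voxels,
            settings.ghost_zone_scale_long,
            settings.ghost_zone_scale_perp,
            series.phase_encode_axis,
        )
        ghost_filter(clusters, zones)
    if manual_decisions is not None:
        manual_censor(clusters, manual_decisions)

    for c in clusters:
        if c.status == "candidate":
            c.status = "included"

    included = [c for c in clusters if c.status == "included"]
    for c in included:
        c.trace = extract_trace(maps.velocity, c, sign_flip=profile.sign_flip)
        mean = c.trace.mean()
        c.v_mean = float(mean)
        c.pi = pulsatility_index(c.trace) if mean != 0 else None

    n_detected, v_mean_pooled, mean_norm_trace, pi = pooled_outcomes(included)
    mean_snr_v = (
        float(sum(abs(c.mean_snr_v) for c in included) / len(included))
        if included
        else None
    )

    return StudyResult(
        clusters=clusters,
        n_detected=n_detected,
        v_mean_pooled=v_mean_pooled,
        mean_norm_trace=mean_norm_trace,
        pi=pi,
        mean_snr_v=mean_snr_v,
        settings=settings,
        location=series.location,
        effective_threshold=effective_t_n,
        version=__version__,
    )


def run_single(
    scan_path: str | Path,
    mask_path: str | Path,
    location: str,
    settings: AnalysisSettings | None = None,
    out_dir: str | Path | None = None,
    manual_decisions: dict[int, str] | None = None,
    stem: str | None = None,
) -> StudyResult:
    """Analyze one scan from disk and (optionally) write its result files."""
    settings = settings or AnalysisSettings()
    series = read_series(scan_path, settings=settings, location=location)
    roi = read_roi_mask(mask_path, series)
    result = analyze(series, roi, settings, manual_decisions=manual_decisions)
    if out_dir is not None:
        write_results(result, out_dir, stem=stem or Path(scan_path).stem.split(".")[0])
    return result
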