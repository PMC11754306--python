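"""Input/output for 2D cine phase-contrast MRI data.

Reads cine magnitude/phase series from DICOM or from the package's
single-file fixture container, reads ROI masks, and writes per-vessel and
summary result tables together with a provenance sidecar (tool version plus
every analysis setting) so that a run can be reproduced from its outputs
alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CineSeries",
    "RoiMask",
    "AnalysisSettings",
    "IncompleteCineError",
    "PhaseDialectError",
    "MissingVencError",
    "GridMismatchError",
    "EmptyRoiError",
    "read_dicom_series",
    "read_fixture",
    "write_fixture",
    "read_series",
    "read_roi_mask",
    "write_results",
    "DEFAULT_VENC_TAGS",
]

LOCATIONS = ("basal_ganglia", "semioval_center")

# Candidate DICOM elements that may hold the velocity encoding (cm/s).
# (0018,9217) is the standard Velocity Encoding Maximum Value; (2001,101A)
# is a Philips private triple. Vendors vary, so the list is configurable.
DEFAULT_VENC_TAGS: tuple[tuple[int, int], ...] = ((0x0018, 0x9217), (0x2001, 0x101A))

# Span of stored integers in the scaled_integer phase dialect: stored value s
# maps to s * pi / 4096 radians, covering [-pi, pi).
PHASE_INT_HALF_RANGE = 4096


class IncompleteCineError(ValueError):
    """Magnitude/phase frames cannot be paired into a complete cine."""


class PhaseDialectError(ValueError):
    """Rescaled phase values are outside the representable range."""


class MissingVencError(ValueError):
    """No velocity encoding in the header and none configured."""


class GridMismatchError(ValueError):
    """Mask shape does not match the series in-plane shape."""


class EmptyRoiError(ValueError):
    """ROI mask contains no voxels."""


@dataclass
class CineSeries:
    """A 2D cine PC-MRI acquisition: magnitude and phase over the cardiac cycle.

    Arrays are indexed ``(row, col, cardiac_phase)``; phase values are radians
    in ``[-pi, pi)``. ``venc_cm_s`` is the velocity that maps to a phase of
    ``±pi``; velocities beyond it alias.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    venc_cm_s: float
    temporal_resolution_ms: float
    location: str = "basal_ganglia"
    phase_encode_axis: str = "row"

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.ndim != 3 or self.phase.ndim != 3:
            raise ValueError("magnitude and phase must be 3D (row, col, phase)")
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must have identical shape")
        if self.n_phases < 2:
            raise IncompleteCineError("cine needs at least 2 cardiac phases")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude values must be non-negative")
        # allow the +pi endpoint within float rounding of a stored -pi..pi grid
        if np.any(self.phase < -np.pi - 1e-9) or np.any(self.phase >= np.pi + 1e-9):
            raise PhaseDialectError("phase values must lie in [-pi, pi) radians")
        if not (self.pixel_spacing_mm[0] > 0 and self.pixel_spacing_mm[1] > 0):
            raise ValueError("pixel spacing must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")
        if self.temporal_resolution_ms <= 0:
            raise ValueError("temporal resolution must be positive")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")
        if self.phase_encode_axis not in ("row", "col"):
            raise ValueError("phase_encode_axis must be 'row' or 'col'")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[2]

    @property
    def in_plane_shape(self) -> tuple[int, int]:
        return self.magnitude.shape[:2]


@dataclass
class RoiMask:
    """Binary inclusion region on the image grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise EmptyRoiError("ROI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


@dataclass
class AnalysisSettings:
    """All user-settable options and thresholds of the analysis.

    Every field is logged to the provenance sidecar of each run.

    Parameters
    ----------
    alpha
        Two-sided significance level for the noise threshold T_n
        (default 0.05, giving T_n = 1.96).
    median_kernel_mm
        Edge length of the square median-filter kernel used for the noise
        map and the background-velocity map, in mm (default 10).
    axes_ratio_max
        Clusters whose moment-ellipse axes ratio exceeds this are discarded
        as in-plane vessels (default 2).
    dedup_distance_mm
        Of detections closer than this, only the highest-velocity one is
        kept (default 1.2 mm).
    erosion_voxels
        Number of single-voxel erosion passes applied to the ROI edge
        (default 80); by default active only for semioval-center scans.
    ghost_percentile
        Top magnitude percentile (in percent, default 0.3) defining bright
        in-plane vessels that seed ghosting exclusion zones.
    temporal_statistic
        Per-voxel reduction of the per-frame velocity SNR used for
        detection: ``"mean"`` (plain temporal mean, default) or
        ``"mean_zscore"`` (mean times sqrt(n_phases), the size-alpha
        z-test of zero mean velocity).
    """

    alpha: float = 0.05
    median_kernel_mm: float = 10.0
    axes_ratio_max: float = 2.0
    dedup_distance_mm: float = 1.2
    erosion_voxels: int = 80
    ghost_percentile: float = 0.3
    ghost_min_cluster_voxels: int = 5
    ghost_zone_scale_long: float = 10.0
    ghost_zone_scale_perp: float = 2.0
    tn_scaling_factor: float = 1.0
    enable_shape_filter: bool = True
    enable_dedup: bool = True
    enable_ghost_filter: bool = True
    enable_erosion: bool | None = None  # None: only for semioval_center
    phase_dialect: str = "radians"
    connectivity: int = 4
    temporal_statistic: str = "mean"
    venc_cm_s: float | None = None  # fallback when absent from the header
    venc_tags: tuple[tuple[int, int], ...] = DEFAULT_VENC_TAGS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        _positive("median_kernel_mm", self.median_kernel_mm)
        _positive("axes_ratio_max", self.axes_ratio_max)
        _positive("dedup_distance_mm", self.dedup_distance_mm)
        if self.erosion_voxels < 0:
            raise ValueError("erosion_voxels must be >= 0")
        if not 0 < self.ghost_percentile < 100:
            raise ValueError("ghost_percentile must lie in (0, 100)")
        if self.ghost_min_cluster_voxels < 1:
            raise ValueError("ghost_min_cluster_voxels must be >= 1")
        _positive("ghost_zone_scale_long", self.ghost_zone_scale_long)
        _positive("ghost_zone_scale_perp", self.ghost_zone_scale_perp)
        _positive("tn_scaling_factor", self.tn_scaling_factor)
        if self.phase_dialect not in ("radians", "scaled_integer"):
            raise ValueError("phase_dialect must be 'radians' or 'scaled_integer'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.temporal_statistic not in ("mean", "mean_zscore"):
            raise ValueError("temporal_statistic must be 'mean' or 'mean_zscore'")

    def erosion_active(self, location: str) -> bool:
        if self.enable_erosion is None:
            return location == "semioval_center"
        return self.enable_erosion

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["venc_tags"] = [list(t) for t in self.venc_tags]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSettings":
        d = dict(d)
        if "venc_tags" in d:
            d["venc_tags"] = tuple(tuple(t) for t in d["venc_tags"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisSettings":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# DICOM reading


def _frame_phase_values(stored: np.ndarray, slope: float, intercept: float,
                        dialect: str) -> np.ndarray:
    vals = stored * slope + intercept
    if dialect == "scaled_integer":
        vals = vals * np.pi / PHASE_INT_HALF_RANGE
    out_of_range = (vals < -np.pi - 1e-6) | (vals >= np.pi + 1e-6)
    if np.any(out_of_range):
        raise PhaseDialectError(
            "rescaled phase values fall outside [-pi, pi); check phase_dialect"
        )
    return np.clip(vals, -np.pi, np.nextafter(np.pi, -np.inf))


def _is_phase_frame(ds) -> bool:
    image_type = [str(v).upper() for v in getattr(ds, "ImageType", [])]
    for token in image_type:
        if token in ("P", "PHASE", "P_PC", "VELOCITY", "PHASE CONTRAST P"):
            return True
    return False


def _is_magnitude_frame(ds) -> bool:
    image_type = [str(v).upper() for v in getattr(ds, "ImageType", [])]
    for token in image_type:
        if token in ("M", "MAG", "MAGNITUDE", "M_PC"):
            return True
    return False


def _venc_from_header(ds, tags: Sequence[tuple[int, int]]) -> float | None:
    for group, elem in tags:
        if (group, elem) in ds:
            value = ds[(group, elem)].value
            try:
                if isinstance(value, (list, tuple)) or getattr(value, "__len__", None) and not isinstance(value, (str, bytes)):
                    value = [float(v) for v in value]
                    value = max(abs(v) for v in value)
                else:
                    value = abs(float(value))
            except (TypeError, ValueError):
                continue
            if value > 0:
                return float(value)
    return None


def read_dicom_series(
    path: str | Path,
    settings: AnalysisSettings | None = None,
    location: str = "basal_ganglia",
) -> CineSeries:
    """Read a cine PC-MRI series from a directory of single-frame DICOM files.

    Frames are paired into (magnitude, phase) per cardiac trigger time using
    their image-type tags and sorted by trigger time. Phase is rescaled to
    radians via the stored slope/intercept according to
    ``settings.phase_dialect``. The velocity encoding is taken from the
    configured candidate header tags, falling back to
    ``settings.venc_cm_s``.
    """
    import pydicom

    settings = settings or AnalysisSettings()
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
    else:
        files = [path]
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM clutter in the folder
            continue
    if not datasets:
        raise IncompleteCineError(f"no DICOM frames found under {path}")

    mag_frames: dict[float, object] = {}
    phase_frames: dict[float, object] = {}
    for ds in datasets:
        t = float(getattr(ds, "TriggerTime", len(mag_frames)))
        if _is_phase_frame(ds):
            phase_frames[t] = ds
        elif _is_magnitude_frame(ds):
            mag_frames[t] = ds
        else:
            raise IncompleteCineError(
                "frame with unrecognized image type: cannot pair magnitude/phase"
            )
    if set(mag_frames) != set(phase_frames) or len(mag_frames) < 2:
        raise IncompleteCineError(
            f"incomplete cine: {len(mag_frames)} magnitude vs "
            f"{len(phase_frames)} phase trigger times"
        )

    times = sorted(mag_frames)
    mags, phases = [], []
    for t in times:
        m = mag_frames[t]
        p = phase_frames[t]
        m_slope = float(getattr(m, "RescaleSlope", 1.0))
        m_inter = float(getattr(m, "RescaleIntercept", 0.0))
        mags.append(m.pixel_array.astype(float) * m_slope + m_inter)
        p_slope = float(getattr(p, "RescaleSlope", 1.0))
        p_inter = float(getattr(p, "RescaleIntercept", 0.0))
        phases.append(
            _frame_phase_values(
                p.pixel_array.astype(float), p_slope, p_inter, settings.phase_dialect
            )
        )

    ref = mag_frames[times[0]]
    venc = _venc_from_header(ref, settings.venc_tags)
    if venc is None:
        venc = settings.venc_cm_s
    if venc is None:
        raise MissingVencError(
            "no velocity encoding found in the DICOM header and none configured"
        )
    spacing = getattr(ref, "PixelSpacing", None)
    spacing = (float(spacing[0]), float(spacing[1])) if spacing else (1.0, 1.0)
    thickness = float(getattr(ref, "SliceThickness", 1.0))
    if len(times) > 1:
        dt = float(np.median(np.diff(times)))
    else:
        dt = 1.0
    in_plane = getattr(ref, "InPlanePhaseEncodingDirection", "ROW")
    pe_axis = "row" if str(in_plane).upper().startswith("ROW") else "col"

    return CineSeries(
        magnitude=np.stack(mags, axis=-1),
        phase=np.stack(phases, axis=-1),
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        venc_cm_s=float(venc),
        temporal_resolution_ms=dt if dt > 0 else 1.0,
        location=location,
        phase_encode_axis=pe_axis,
    )


# ---------------------------------------------------------------------------
# Fixture container: a single .npz archive holding the two cine grids plus a
# JSON metadata record. Documented, DICOM-free interchange for tests and
# phantom output.

FIXTURE_SUFFIX = ".pcmri.npz"


def write_fixture(series: CineSeries, path: str | Path) -> Path:
    """Write a CineSeries to the single-file fixture container (.pcmri.npz)."""
    path = Path(path)
    if not str(path).endswith(FIXTURE_SUFFIX):
        path = Path(str(path) + FIXTURE_SUFFIX)
    meta = {
        "pixel_spacing_mm": list(series.pixel_spacing_mm),
        "slice_thickness_mm": series.slice_thickness_mm,
        "venc_cm_s": series.venc_cm_s,
        "n_phases": series.n_phases,
        "temporal_resolution_ms": series.temporal_resolution_ms,
        "location": series.location,
        "phase_encode_axis": series.phase_encode_axis,
    }
    np.savez(
        path,
        magnitude=series.magnitude,
        phase=series.phase,
        meta=np.array(json.dumps(meta)),
    )
    return path


def read_fixture(path: str | Path) -> CineSeries:
    """Read a CineSeries from the fixture container written by write_fixture."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        return CineSeries(
            magnitude=npz["magnitude"],
            phase=npz["phase"],
            pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
            slice_thickness_mm=meta["slice_thickness_mm"],
            venc_cm_s=meta["venc_cm_s"],
            temporal_resolution_ms=meta["temporal_resolution_ms"],
            location=meta["location"],
            phase_encode_axis=meta["phase_encode_axis"],
        )


def read_series(
    path: str | Path,
    settings: AnalysisSettings | None = None,
    location: str = "basal_ganglia",
) -> CineSeries:
    """Read a cine series from either the fixture container or DICOM."""
    path = Path(path)
    if str(path).endswith(FIXTURE_SUFFIX) or path.suffix == ".npz":
        series = read_fixture(path)
        series.location = location
        return series
    return read_dicom_series(path, settings=settings, location=location)


# ---------------------------------------------------------------------------
# ROI masks


def read_roi_mask(path: str | Path, series: CineSeries) -> RoiMask:
    """Read a binary ROI mask (NPY or single-channel image); nonzero → True."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path, allow_pickle=False)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse channels
            arr = arr[..., 0]
    if arr.ndim != 2 or arr.shape != series.in_plane_shape:
        raise GridMismatchError(
            f"mask shape {arr.shape} does not match series {series.in_plane_shape}"
        )
    if not np.any(arr):
        raise EmptyRoiError(f"mask at {path} contains no voxels")
    return RoiMask(arr != 0)


# ---------------------------------------------------------------------------
# Result writing


def write_results(result, out_dir: str | Path, stem: str = "result") -> dict[str, Path]:
    """Write the per-vessel table, summary record, and provenance sidecar.

    Returns a mapping of output kind to path. Tables are deterministic:
    writing the same result twice produces byte-identical CSV files (the
    provenance timestamp lives only in the JSON sidecar).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for c in result.clusters:
        row = {
            "vessel_id": c.cluster_id,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "centroid_row_mm": c.centroid_mm[0],
            "centroid_col_mm": c.centroid_mm[1],
            "n_voxels": c.n_voxels,
            "axes_ratio": c.axes_ratio if c.axes_ratio is not None else np.nan,
            "v_mean_cm_s": c.v_mean if c.v_mean is not None else np.nan,
            "pi": c.pi if c.pi is not None else np.nan,
            "mean_snr_v": c.mean_snr_v if c.mean_snr_v is not None else np.nan,
            "status": c.status,
        }
        if c.trace is not None:
            for t, v in enumerate(c.trace):
                row[f"v_phase_{t:02d}_cm_s"] = v
        rows.append(row)
    vessel_df = pd.DataFrame(rows)
    vessels_path = out_dir / f"{stem}_vessels.csv"
    vessel_df.to_csv(vessels_path, index=False, float_format="%.6g")

    summary = {
        "n_detected": result.n_detected,
        "v_mean_cm_s": result.v_mean_pooled if result.n_detected else np.nan,
        "pi": result.pi if result.n_detected else np.nan,
        "mean_snr_v": result.mean_snr_v if result.n_detected else np.nan,
    }
    summary_path = out_dir / f"{stem}_summary.csv"
    pd.DataFrame([summary]).to_csv(summary_path, index=False, float_format="%.6g")

    import datetime

    provenance = {
        "tool": "perfvel",
        "version": result.version,
        "timestamp": datetime.datetime.now().isoformat(),
        "settings": result.settings.to_dict(),
        "location": result.location,
        "effective_noise_threshold": result.effective_threshold,
    }
    prov_path = out_dir / f"{stem}_provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {"vessels": vessels_path, "summary": summary_path, "provenance": prov_path}
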