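"""Per-vessel velocity traces and pooled outcome measures.

The three study outcomes are the number of included perforating arteries
(N_detected), their mean blood-flow velocity v_mean (cm/s), and the velocity
pulsatility index PI = (v_max - v_min) / v_mean of the pooled cardiac-cycle
trace. For pooling, each vessel's trace is first normalized by its own
temporal mean, then traces are averaged pointwise (mean estimator); the
pooled trace has temporal mean 1.0 by construction, so the pooled PI is
simply max - min of that trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detect import VesselCluster
from .io import AnalysisSettings

__all__ = ["StudyResult", "extract_trace", "pulsatility_index", "pooled_outcomes"]


@dataclass
class StudyResult:
    """Pooled outcomes plus the per-cluster records and run provenance."""

    clusters: list[VesselCluster]
    n_detected: int
    v_mean_pooled: float | None
    mean_norm_trace: np.ndarray | None
    pi: float | None
    mean_snr_v: float | None
    settings: AnalysisSettings
    location: str
    effective_threshold: float
    version: str = ""

    @property
    def vessels(self) -> list[VesselCluster]:
        """Clusters with status ``included``."""
        return [c for c in self.clusters if c.status == "included"]


def extract_trace(
    velocity: np.ndarray, cluster: VesselCluster, sign_flip: bool = False
) -> np.ndarray:
    """Velocity trace at the cluster's peak voxel, one value per cardiac phase.

    ``sign_flip`` negates the trace for territories where flow runs out of
    the slice (semioval center), so reported mean velocities are positive.
    """
    r, c = cluster.peak_voxel
    trace = np.asarray(velocity[r, c, :], dtype=float)
    return -trace if sign_flip else trace.copy()


def pulsatility_index(trace: np.ndarray) -> float:
    """PI = (max - min) / mean of a single velocity trace."""
    trace = np.asarray(trace, dtype=float)
    mean = trace.mean()
    if mean == 0:
        raise ValueError("PI undefined for a zero-mean trace")
    return float((trace.max() - trace.min()) / mean)


def pooled_outcomes(
    included: list[VesselCluster],
) -> tuple[int, float | None, np.ndarray | None, float | None]:
    """Pool included vessels into (n_detected, v_mean, mean normalized trace, PI).

    Each vessel's trace is divided by its own temporal mean before
    averaging; a vessel whose trace mean is zero cannot be normalized and is
    dropped from pooling with a warning. The pooled PI uses denominator 1.0
    (the pooled normalized trace has unit mean); v_mean is the plain average
    of the unnormalized per-vessel temporal means.
    """
    usable = []
    for c in included:
        if c.trace is None:
            raise ValueError(f"cluster {c.cluster_id} has no trace")
        if np.asarray(c.trace).mean() == 0:
            warnings.warn(
                f"cluster {c.cluster_id} has a zero-mean trace; "
                "excluded from pooled outcomes",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        usable.append(c)
    n_detected = len(included)
    if not usable:
        return n_detected, None, None, None
    traces = np.array([np.asarray(c.trace, float) for c in usable])
    means = traces.mean(axis=1)
    normalized = traces / means[:, None]
    mean_norm_trace = normalized.mean(axis=0)
    pi = float(mean_norm_trace.max() - mean_norm_trace.min())
    v_mean_pooled = float(means.mean())
    return n_detected, v_mean_pooled, mean_norm_trace, pi
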