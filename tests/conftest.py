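"""Shared fixtures: small, fast phantom scenes reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perfvel import AnalysisSettings, RoiMask
from perfvel import phantom as ph

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scene():
    """A reduced study-like scene: 6 perforators on a 160x160 grid."""
    spec, roi = ph.default_scene(
        seed=11,
        n_vessels=6,
        shape=(160, 160),
        roi_radius_mm=20.0,
    )
    series, truth = ph.generate(spec)
    return series, roi, truth


@pytest.fixture(scope="session")
def noise_maps():
    """SNR maps of a flow-free 128x128 scene, for null-distribution tests."""
    from perfvel.noise import compute_maps

    spec, roi = ph.noise_scene(seed=5, shape=(128, 128))
    series, _ = ph.generate(spec)
    return compute_maps(series, 10.0, roi), roi


@pytest.fixture
def clean_series():
    """Tiny noiseless series: one constant 4 cm/s vessel in static tissue."""
    spec = ph.PhantomSpec(
        shape=(48, 48),
        pixel_spacing_mm=(0.3, 0.3),
        n_phases=8,
        noise_sigma=0.0,
        vessels=[ph.PhantomVessel(row=24, col=24, v0_cm_s=4.0)],
        seed=0,
    )
    series, truth = ph.generate(spec)
    return series, truth


def make_series(magnitude, phase, venc=20.0, spacing=(1.0, 1.0), **kw):
    """Build a CineSeries directly from arrays (helper, not a fixture)."""
    from perfvel import CineSeries

    return CineSeries(
        magnitude=np.asarray(magnitude, float),
        phase=np.asarray(phase, float),
        pixel_spacing_mm=spacing,
        slice_thickness_mm=2.0,
        venc_cm_s=venc,
        temporal_resolution_ms=100.0,
        **kw,
    )
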