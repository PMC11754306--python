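"""Noise estimation, SNR maps, velocity scaling, and background correction."""

import numpy as np
import pytest
from scipy import stats

from perfvel import phantom as ph
from perfvel.noise import (
    background_correct,
    compute_maps,
    compute_sigma_v,
    compute_snr_mag,
    compute_snr_v,
    estimate_noise_map,
    kernel_voxels,
    median_smooth,
    phase_to_velocity,
)

from conftest import make_series


class TestKernel:
    def test_default_protocol_kernel_is_33(self):
        assert kernel_voxels(10.0, (0.3, 0.3)) == 33

    def test_even_rounding_forced_odd(self):
        assert kernel_voxels(10.0, (0.5, 0.5)) == 21
        assert kernel_voxels(8.0, (1.0, 1.0)) == 9  # round(8) even -> 9

    def test_subvoxel_kernel_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            kernel_voxels(0.1, (0.3, 0.3))


class TestMedianSmooth:
    def test_constant_preserved_exactly_both_paths(self):
        for shape in ((64, 64), (400, 400)):  # exact and quantized paths
            img = np.full(shape, 3.7)
            np.testing.assert_array_equal(median_smooth(img, 33), img)

    def test_quantized_path_matches_exact_within_bin(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 1, (120, 120))
        from perfvel import noise as noise_mod

        exact = median_smooth(img, 21)
        # force the rank path on the same image
        old = noise_mod._EXACT_MEDIAN_MAX_PIXELS
        noise_mod._EXACT_MEDIAN_MAX_PIXELS = 0
        try:
            approx = median_smooth(img, 21)
        finally:
            noise_mod._EXACT_MEDIAN_MAX_PIXELS = old
        bin_width = (img.max() - img.min()) / 4095
        assert np.abs(exact - approx).max() <= 1.01 * bin_width


class TestNoiseEstimate:
    def test_static_voxel_has_zero_noise(self):
        series = make_series(
            np.full((8, 8, 6), 5.0), np.full((8, 8, 6), 0.3), spacing=(1.0, 1.0)
        )
        noise = estimate_noise_map(series, kernel_mm=1.0)  # 1-voxel kernel
        np.testing.assert_allclose(noise, 0.0, atol=1e-12)

    def test_monte_carlo_recovers_channel_sigma(self):
        """Complex noise with per-channel std sigma -> estimate -> sigma."""
        rng = np.random.default_rng(42)
        sigma = 1.7
        re = rng.normal(0, sigma, (100, 100, 1000))
        im = rng.normal(0, sigma, (100, 100, 1000))
        series = make_series(np.abs(re + 1j * im), np.angle(re + 1j * im))
        noise = estimate_noise_map(series, kernel_mm=1.0)
        assert abs(noise.mean() - sigma) / sigma < 0.03

    def test_single_phase_rejected(self):
        # the CineSeries type itself already forbids < 2 phases
        with pytest.raises(ValueError):
            make_series(np.ones((4, 4, 1)), np.zeros((4, 4, 1)))


class TestSnrMag:
    def test_constant_ratio(self):
        series = make_series(np.full((4, 4, 3), 100.0), np.zeros((4, 4, 3)))
        snr, snr_mean = compute_snr_mag(series, np.full((4, 4), 10.0))
        np.testing.assert_allclose(snr, 10.0)
        np.testing.assert_allclose(snr_mean, 10.0)

    def test_temporal_mean_is_arithmetic(self):
        mag = np.zeros((2, 2, 4))
        for t in range(4):
            mag[..., t] = 10.0 * (t + 1)
        series = make_series(mag, np.zeros_like(mag))
        _, snr_mean = compute_snr_mag(series, np.full((2, 2), 10.0))
        np.testing.assert_allclose(snr_mean, 2.5)

    def test_zero_noise_guard_warns_and_substitutes(self):
        from perfvel import RoiMask

        series = make_series(np.ones((4, 4, 3)), np.zeros((4, 4, 3)))
        noise = np.full((4, 4), 0.5)
        noise[1, 1] = 0.0
        roi = RoiMask(np.ones((4, 4), bool))
        with pytest.warns(RuntimeWarning, match="non-positive"):
            snr, _ = compute_snr_mag(series, noise, roi)
        assert np.isfinite(snr).all()
        assert snr[1, 1, 0] == pytest.approx(1 / 0.5)


class TestPhaseToVelocity:
    @pytest.mark.parametrize(
        "phi,venc,expected",
        [(np.pi / 2, 20.0, 10.0), (0.0, 20.0, 0.0), (-np.pi, 20.0, -20.0)],
    )
    def test_linear_map(self, phi, venc, expected):
        series = make_series(np.ones((2, 2, 3)), np.full((2, 2, 3), phi), venc=venc)
        np.testing.assert_allclose(phase_to_velocity(series), expected)

    def test_bounded_by_venc(self, small_scene):
        series, _, _ = small_scene
        v = phase_to_velocity(series)
        assert np.abs(v).max() <= series.venc_cm_s


class TestBackgroundCorrect:
    def test_uniform_offset_removed(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, (40, 40, 5))
        corrected = background_correct(v, 5.0, (1.0, 1.0))
        shifted = background_correct(v + 3.3, 5.0, (1.0, 1.0))
        np.testing.assert_allclose(shifted, corrected, atol=1e-10)

    def test_smooth_plane_centers_to_zero(self):
        """Static tissue over a smooth background plane ends up near zero."""
        rows = np.arange(64)[:, None, None]
        cols = np.arange(64)[None, :, None]
        venc = 20.0
        v = (0.5 + 0.004 * rows + 0.006 * cols) * np.ones((1, 1, 6))
        corrected = background_correct(v, 10.0, (0.3, 0.3))
        assert np.abs(corrected.mean(axis=2)).max() < 0.01 * venc

    def test_vessel_survives_correction(self, clean_series):
        """A subvoxel vessel's velocity is untouched by the (median) background."""
        series, truth = clean_series
        v = phase_to_velocity(series)
        corrected = background_correct(v, 10.0, series.pixel_spacing_mm)
        rec = truth["vessels"][0]
        assert corrected[rec["row"], rec["col"]].mean() == pytest.approx(4.0, abs=0.05)

    def test_idempotent_on_smooth_fields(self):
        rows = np.arange(64)[:, None, None]
        v = (1.0 + 0.02 * rows) * np.ones((1, 64, 6))
        once = background_correct(v, 10.0, (0.3, 0.3))
        twice = background_correct(once, 10.0, (0.3, 0.3))
        np.testing.assert_allclose(twice, once, atol=1e-9)


class TestSigmaV:
    @pytest.mark.parametrize(
        "venc,snr,expected",
        [(np.pi, 1.0, 1.0), (20.0, 10.0, 20.0 / (10 * np.pi))],
    )
    def test_formula(self, venc, snr, expected):
        out = compute_sigma_v(venc, np.full((3, 3), snr))
        np.testing.assert_allclose(out, expected)

    def test_homogeneity(self):
        """sigma_v scales linearly in venc and inversely in SNR_mag."""
        rng = np.random.default_rng(2)
        snr = rng.uniform(1, 30, (20, 20))
        base = compute_sigma_v(20.0, snr)
        np.testing.assert_allclose(compute_sigma_v(40.0, snr), 2 * base)
        np.testing.assert_allclose(compute_sigma_v(20.0, 2 * snr), base / 2)


class TestSnrV:
    def test_constant_ratio(self):
        v = np.full((2, 2, 3), 1.2732)
        snr_v, snr_v_mean = compute_snr_v(v, np.full((2, 2), 0.6366))
        np.testing.assert_allclose(snr_v, 2.0, rtol=1e-4)
        np.testing.assert_allclose(snr_v_mean, 2.0, rtol=1e-4)

    def test_zero_velocity_zero_snr(self):
        snr_v, _ = compute_snr_v(np.zeros((2, 2, 3)), np.ones((2, 2)))
        np.testing.assert_array_equal(snr_v, 0.0)


class TestNullDistribution:
    def test_per_frame_snr_v_is_standard_normal(self, noise_maps):
        """On a flow-free phantom the per-frame velocity z-scores are ~N(0,1)."""
        maps, roi = noise_maps
        rng = np.random.default_rng(9)
        sample = maps.snr_v[roi.mask].ravel()
        sample = rng.choice(sample, 10000, replace=False)
        _, p = stats.kstest(sample, "norm")
        assert p > 0.01

    def test_temporal_mean_is_shrunk_by_averaging(self, noise_maps):
        """The temporal-mean SNR_v has null std ~1/sqrt(n_phases), so
        essentially no flow-free voxel exceeds the 1.96 threshold."""
        maps, roi = noise_maps
        n = maps.snr_v.shape[2]
        vals = maps.snr_v_mean[roi.mask]
        assert vals.std() == pytest.approx(1 / np.sqrt(n), rel=0.15)
        assert (vals > 1.96).mean() < 1e-3

    def test_mean_zscore_statistic_is_calibrated(self, noise_maps):
        """The z-scored mean exceeds 1.96 at ~alpha/2 under the null."""
        maps, roi = noise_maps
        stat = maps.detection_statistic("mean_zscore")[roi.mask]
        assert 0.015 <= (stat > 1.96).mean() <= 0.035


def test_compute_maps_is_consistent(small_scene):
    series, roi, _ = small_scene
    maps = compute_maps(series, 10.0, roi)
    np.testing.assert_allclose(
        maps.sigma_v, series.venc_cm_s / (np.pi * maps.snr_mag_mean), rtol=1e-12
    )
    np.testing.assert_allclose(maps.snr_v_mean, maps.snr_v.mean(axis=2), rtol=1e-12)
    # centering: median-filtered temporal-mean corrected velocity ~ 0
    from perfvel.noise import kernel_voxels as kv, median_smooth as ms

    edge = kv(10.0, series.pixel_spacing_mm)
    centered = ms(maps.velocity.mean(axis=2), edge)
    assert np.abs(centered[roi.mask]).max() < 0.01 * series.venc_cm_s
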