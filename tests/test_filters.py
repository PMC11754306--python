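"""Shape filter, deduplication, ROI erosion, ghost zones, manual censoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from perfvel import RoiMask
from perfvel.detect import VesselCluster
from perfvel.filters import (
    ExclusionZone,
    axes_ratio,
    bright_vessel_zones,
    deduplicate,
    erode_roi,
    ghost_filter,
    manual_censor,
    read_censor_decisions,
    shape_filter,
)
from perfvel.io import EmptyRoiError


def cluster(voxels, cid=0, v_mean=None, spacing=1.0):
    voxels = np.asarray(voxels)
    centroid = tuple(voxels.mean(axis=0))
    return VesselCluster(
        cluster_id=cid,
        voxels=voxels,
        centroid=centroid,
        centroid_mm=(centroid[0] * spacing, centroid[1] * spacing),
        peak_voxel=tuple(voxels[0]),
        v_mean=v_mean,
    )


class TestErodeRoi:
    def test_zero_passes_is_identity(self):
        roi = RoiMask(np.ones((9, 9), bool))
        out = erode_roi(roi, 0)
        np.testing.assert_array_equal(out.mask, roi.mask)

    def test_square_erodes_to_center(self):
        roi = RoiMask(np.ones((21, 21), bool))
        out = erode_roi(roi, 10)
        assert out.n_voxels == 1
        assert out.mask[10, 10]

    def test_over_erosion_raises(self):
        roi = RoiMask(np.ones((21, 21), bool))
        with pytest.raises(EmptyRoiError):
            erode_roi(roi, 11)


class TestAxesRatio:
    def test_single_voxel(self):
        assert axes_ratio(cluster([(3, 3)])) == pytest.approx(1.0)

    def test_square_block(self):
        assert axes_ratio(cluster([(0, 0), (0, 1), (1, 0), (1, 1)])) == pytest.approx(1.0)

    def test_bar_1x6(self):
        """Second-moment ellipse of a discrete 1x6 bar: sqrt(35) ~ 5.92."""
        bar = [(0, c) for c in range(6)]
        assert axes_ratio(cluster(bar)) == pytest.approx(np.sqrt(35), rel=1e-12)

    def test_disc_is_round(self):
        rr, cc = np.nonzero(
            (np.arange(9)[:, None] - 4) ** 2 + (np.arange(9)[None, :] - 4) ** 2 <= 16
        )
        assert axes_ratio(cluster(np.column_stack([rr, cc]))) == pytest.approx(1.0)

    def test_diagonal_bar_also_elongated(self):
        # principal axes follow the point set, not the grid: the long
        # eigenvalue doubles (row+col variance), the floor still applies
        bar = [(c, c) for c in range(6)]
        assert axes_ratio(cluster(bar)) == pytest.approx(np.sqrt(70), rel=1e-12)


class TestShapeFilter:
    def test_threshold_is_strict(self):
        kept = cluster([(0, 0)], cid=0)
        kept.axes_ratio = 2.0  # exactly at threshold: "exceeds" is strict
        gone = cluster([(5, 5)], cid=1)
        gone.axes_ratio = 5.92
        shape_filter([kept, gone], axes_ratio_max=2.0)
        assert kept.status == "candidate"
        assert gone.status == "excluded_shape"

    def test_ratio_computed_when_missing(self):
        bar = cluster([(0, c) for c in range(6)])
        shape_filter([bar], 2.0)
        assert bar.status == "excluded_shape"
        assert bar.axes_ratio == pytest.approx(np.sqrt(35))


class TestDeduplicate:
    def test_pair_within_distance_keeps_fastest(self):
        a = cluster([(0, 0)], 0, v_mean=5.0)
        b = cluster([(0, 1)], 1, v_mean=3.0)  # 1.0 mm apart
        deduplicate([a, b], 1.2)
        assert a.status == "candidate" and b.status == "excluded_duplicate"

    def test_pair_beyond_distance_both_kept(self):
        a = cluster([(0, 0)], 0, v_mean=5.0)
        b = cluster([(0, 1.3)], 1, v_mean=3.0)
        deduplicate([a, b], 1.2)
        assert a.status == b.status == "candidate"

    def test_collinear_triple_keeps_middle_only(self):
        """0/1/2 mm line with velocities 3,5,4: greedy keeps only the middle."""
        c0 = cluster([(0, 0)], 0, v_mean=3.0)
        c1 = cluster([(0, 1)], 1, v_mean=5.0)
        c2 = cluster([(0, 2)], 2, v_mean=4.0)
        deduplicate([c0, c1, c2], 1.2)
        assert c1.status == "candidate"
        assert c0.status == c2.status == "excluded_duplicate"

    def test_negative_velocities_compared_by_magnitude(self):
        a = cluster([(0, 0)], 0, v_mean=-5.0)
        b = cluster([(0, 1)], 1, v_mean=3.0)
        deduplicate([a, b], 1.2)
        assert a.status == "candidate" and b.status == "excluded_duplicate"

    @given(st.integers(0, 10000))
    def test_matches_brute_force_on_random_scenes(self, seed):
        """Greedy suppression == literal rule: every excluded cluster has a
        kept, faster (or tie-earlier) cluster within range; kept clusters are
        pairwise separated."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        clusters = [
            cluster([(float(rng.uniform(0, 6)), float(rng.uniform(0, 6)))], i,
                    v_mean=float(rng.uniform(1, 9)))
            for i in range(n)
        ]
        deduplicate(clusters, 1.2)
        kept = [c for c in clusters if c.status == "candidate"]
        for a in kept:
            for b in kept:
                if a is not b:
                    d = np.hypot(a.centroid_mm[0] - b.centroid_mm[0],
                                 a.centroid_mm[1] - b.centroid_mm[1])
                    assert d >= 1.2
        for c in clusters:
            if c.status == "excluded_duplicate":
                assert any(
                    np.hypot(c.centroid_mm[0] - k.centroid_mm[0],
                             c.centroid_mm[1] - k.centroid_mm[1]) < 1.2
                    and (abs(k.v_mean), k.centroid) != (abs(c.v_mean), c.centroid)
                    for k in kept
                )


class TestBrightVesselZones:
    def _image(self, bright=None):
        img = np.full((100, 100), 10.0)
        if bright:
            r, c, h, w = bright
            img[r : r + h, c : c + w] = 100.0
        return img

    def test_uniform_image_has_no_zone(self):
        # top-percentile voxels exist but never form a >= min-size cluster
        rng = np.random.default_rng(0)
        img = rng.normal(10, 0.1, (100, 100))
        zones = bright_vessel_zones(img, 0.3, 5)
        assert zones == []

    def test_zone_contains_its_cluster(self):
        img = self._image((40, 45, 2, 10))
        zones = bright_vessel_zones(img, 0.3, 5, 10.0, 2.0, "row")
        assert len(zones) == 1
        z = zones[0]
        assert z.row_min <= 40 and z.row_max >= 41
        assert z.col_min <= 45 and z.col_max >= 54
        # long axis along rows (phase encode), clipped to the image
        assert z.row_max - z.row_min > z.col_max - z.col_min

    def test_small_bright_cluster_ignored(self):
        img = self._image((40, 45, 1, 3))  # 3 voxels < min 5
        assert bright_vessel_zones(img, 0.3, 5) == []


class TestGhostFilter:
    def test_candidate_inside_zone_excluded(self):
        z = ExclusionZone(0, 10, 0, 10, source_cluster=1)
        inside = cluster([(5, 5)], 0, v_mean=3.0)
        outside = cluster([(50, 50)], 1, v_mean=3.0)
        ghost_filter([inside, outside], [z])
        assert inside.status == "excluded_ghost"
        assert outside.status == "candidate"

    def test_no_zones_no_change(self):
        c = cluster([(5, 5)], 0)
        ghost_filter([c], [])
        assert c.status == "candidate"


class TestManualCensor:
    def test_decisions_applied(self):
        cs = [cluster([(i, 0)], i) for i in range(3)]
        manual_censor(cs, {0: "keep", 1: "keep", 2: "discard"})
        assert [c.status for c in cs] == ["candidate", "candidate", "excluded_manual"]

    def test_overrides_shape_and_dedup_but_not_ghost(self):
        a = cluster([(0, 0)], 0)
        a.status = "excluded_shape"
        b = cluster([(5, 5)], 1)
        b.status = "excluded_ghost"
        manual_censor([a, b], {0: "keep"})
        assert a.status == "candidate"
        assert b.status == "excluded_ghost"

    def test_missing_decision_raises(self):
        cs = [cluster([(i, 0)], i) for i in range(3)]
        with pytest.raises(ValueError, match="incomplete censor list"):
            manual_censor(cs, {0: "keep", 1: "discard"})

    def test_decision_file_round_trip(self, tmp_path):
        path = tmp_path / "decisions.txt"
        path.write_text("# operator review\n0,keep\n1,discard\n")
        assert read_censor_decisions(path) == {0: "keep", 1: "discard"}
        (tmp_path / "bad.txt").write_text("0,maybe\n")
        with pytest.raises(ValueError):
            read_censor_decisions(tmp_path / "bad.txt")


def test_filters_only_move_status_away_from_candidate(small_scene):
    """The included set is always a subset of the detected candidates."""
    from perfvel.pipeline import analyze

    series, roi, _ = small_scene
    res = analyze(series, roi)
    valid = {
        "included",
        "excluded_shape",
        "excluded_duplicate",
        "excluded_ghost",
        "excluded_manual",
    }
    assert {c.status for c in res.clusters} <= valid
    assert res.n_detected == sum(1 for c in res.clusters if c.status == "included")
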