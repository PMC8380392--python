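"""Support surface, membrane fluorescence, cell counting, colocalization."""

import numpy as np
import pytest

from vestcomp.core import ImageGrid
from vestcomp.imaging import (
    CountingFrame, MembraneROISet, PawQuad, average_counts, colocalization_pct,
    count_cells, membrane_intensity, support_surface,
    support_surface_series, survival_rate,
)


def _quad(fl, fr, rl, rr):
    return PawQuad(FL=fl, FR=fr, RL=rl, RR=rr)


class TestSupportSurface:
    def test_unit_square(self):
        q = _quad((0, 0), (1, 0), (0, 1), (1, 1))
        assert support_surface(q) == pytest.approx(1.0)

    def test_rectangle_matches_triangulation(self):
        q = _quad((0, 0), (3, 0), (0, 2), (3, 2))
        assert support_surface(q) == pytest.approx(6.0)

    def test_random_convex_quads_match_triangulation_oracle(self, rng):
        """Shoelace equals the sum of the two triangle areas of the diagonal split."""
        for _ in range(200):
            pts = rng.uniform(-10, 10, size=(4, 2))
            from scipy.spatial import ConvexHull
            hull = ConvexHull(pts)
            if len(hull.vertices) != 4:
                continue
            v = pts[hull.vertices]          # convex perimeter order
            q = _quad(tuple(v[0]), tuple(v[1]), tuple(v[3]), tuple(v[2]))

            def tri(a, b, c):
                return 0.5 * abs((b[0] - a[0]) * (c[1] - a[1])
                                 - (c[0] - a[0]) * (b[1] - a[1]))

            oracle = tri(v[0], v[1], v[2]) + tri(v[0], v[2], v[3])
            assert support_surface(q) == pytest.approx(oracle)

    def test_rigid_motion_invariance(self, rng):
        pts = np.array([[0, 0], [4, 0.5], [0.5, 3], [4.2, 3.4]])
        q = _quad(*map(tuple, pts))
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + rng.uniform(-5, 5, 2)
        q2 = _quad(*map(tuple, moved))
        assert support_surface(q2) == pytest.approx(support_surface(q))

    def test_degenerate_quad_warns_zero(self):
        q = _quad((0, 0), (1, 1), (0.5, 0.5), (2, 2))   # collinear
        with pytest.warns(UserWarning, match="degenerate"):
            assert support_surface(q) == 0.0

    def test_series_normalization(self):
        sq = lambda side: _quad((0, 0), (side, 0), (0, side), (side, side))
        sessions = {"preop": [sq(2.0)] * 10, "d7": [sq(2.0 * np.sqrt(1.15))] * 10,
                    "d30": [sq(2.0)] * 4}
        out = support_surface_series(sessions)
        assert out["preop"]["ratio"] == pytest.approx(1.0)
        assert out["d7"]["ratio"] == pytest.approx(1.15)
        assert out["d30"]["n_trials"] == 4      # short session recorded, not an error

    def test_series_requires_preop(self):
        with pytest.raises(ValueError, match="preop"):
            support_surface_series({"d7": [_quad((0, 0), (1, 0), (0, 1), (1, 1))]})


def _ring_image(ring_value=100.0, bg_mean=10.0, bg_sd=2.0, size=96, seed=0):
    rng = np.random.default_rng(seed)
    img = np.clip(rng.normal(bg_mean, bg_sd, size=(size, size)), 0, None)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - 60, xx - 60)
    ring = (dist >= 8) & (dist < 11)
    img[ring] = ring_value
    roi = np.argwhere((dist >= 6) & (dist < 13))
    bg = np.argwhere((yy < 25) & (xx < 25))
    return ImageGrid(img), MembraneROISet(background=bg, membranes=[roi]), ring


class TestMembraneIntensity:
    def test_uniform_image_no_measurable_cells(self):
        img, rois, _ = _ring_image(ring_value=10.0, bg_sd=0.5)
        # ring at background level: nothing above mean + 3 sd
        with pytest.warns(UserWarning, match="below threshold"):
            res = membrane_intensity(img, rois)
        assert res["per_cell"] == []
        assert np.isnan(res["mean"])

    def test_constant_ring_value_minus_threshold(self):
        img, rois, _ = _ring_image(ring_value=100.0, bg_mean=10.0, bg_sd=2.0)
        res = membrane_intensity(img, rois)
        assert res["threshold"] == pytest.approx(16.0, abs=0.5)
        assert res["mean"] == pytest.approx(84.0, abs=2.0)

    def test_intensity_ordering_preserved(self):
        vals = []
        for v in (60.0, 90.0, 130.0):
            img, rois, _ = _ring_image(ring_value=v, seed=3)
            vals.append(membrane_intensity(img, rois)["mean"])
        assert vals == sorted(vals)

    def test_threshold_tracks_constant_offset(self):
        img, rois, _ = _ring_image(ring_value=100.0, seed=5)
        res0 = membrane_intensity(img, rois)
        shifted = ImageGrid(img.data + 50.0)
        res1 = membrane_intensity(shifted, rois)
        assert res1["mean"] == pytest.approx(res0["mean"], abs=1e-9)

    def test_small_background_rejected(self):
        img, rois, _ = _ring_image()
        rois.background = rois.background[:10]
        with pytest.raises(ValueError, match="background region"):
            membrane_intensity(img, rois)


class TestCellCounting:
    def test_blank_image_zero(self):
        img = ImageGrid(np.full((64, 64), 10, dtype=np.uint16), pixel_size=1.0)
        frame = CountingFrame(area=400.0, origin=(10.0, 10.0))
        assert count_cells(img, frame) == 0

    def test_planted_blobs_recovered(self, rng):
        size = 96
        img = rng.normal(10, 2, size=(size, size)).clip(0)
        yy, xx = np.mgrid[0:size, 0:size]
        pts = [(20, 20), (20, 60), (50, 40), (70, 20), (70, 70), (40, 75),
                (30, 40), (60, 55), (80, 45), (15, 80), (45, 12), (85, 15)]
        for r, c in pts:
            img += 150 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5 ** 2))
        grid = ImageGrid(img, pixel_size=1.0)
        frame = CountingFrame(area=float(size * size), origin=(0.0, 0.0))
        assert count_cells(grid, frame) == len(pts)

    def test_centroids_outside_frame_excluded(self):
        size = 64
        img = np.full((size, size), 10.0)
        yy, xx = np.mgrid[0:size, 0:size]
        for r, c in ((10, 10), (50, 50)):
            img += 150 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5 ** 2))
        grid = ImageGrid(img, pixel_size=1.0)
        frame = CountingFrame(area=30.0 ** 2, origin=(0.0, 0.0))   # covers (10,10) only
        assert count_cells(grid, frame, threshold=30.0) == 1

    def test_average_counts(self):
        assert average_counts([3, 4, 5] * 3 + [4]) == pytest.approx(4.0)
        with pytest.warns(UserWarning, match="10 ± 2"):
            assert average_counts([3, 4, 5]) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            average_counts([])


class TestColocalization:
    def test_identical_sets_full_match(self, rng):
        pts = rng.uniform(0, 50, size=(12, 2))
        assert colocalization_pct(pts, pts, 1.0) == pytest.approx(100.0)

    def test_disjoint_sets_zero(self):
        a = np.zeros((5, 2))
        b = np.full((5, 2), 40.0)
        assert colocalization_pct(a, b, 3.0) == 0.0

    def test_partial_match_percentage(self, rng):
        marker = np.column_stack([np.arange(20) * 10.0, np.zeros(20)])
        nuclear = marker[:13] + rng.normal(0, 0.2, size=(13, 2))
        assert colocalization_pct(marker, nuclear, 3.0) == pytest.approx(65.0)

    def test_matching_is_one_to_one(self):
        marker = np.array([[0.0, 0.0], [1.0, 0.0]])
        nuclear = np.array([[0.4, 0.0]])     # near both; may match only one
        assert colocalization_pct(marker, nuclear, 3.0) == pytest.approx(50.0)

    def test_no_marker_cells_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(colocalization_pct(np.empty((0, 2)), np.zeros((3, 2)), 1.0))


class TestSurvival:
    def test_equal_counts(self):
        assert survival_rate(20.0, 20.0) == pytest.approx(100.0)

    def test_over_100_flagged(self):
        with pytest.warns(UserWarning, match="above 100"):
            assert survival_rate(10.0, 12.0) == pytest.approx(120.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            survival_rate(0.0, 5.0)
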