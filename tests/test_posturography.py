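"""Barycenter chain: stance detection, statokinesigram, dispersion, circling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vestcomp.core import PAWS, TrackingTrajectory
from vestcomp.posturography import (
    MissingBaselineWarning, Statokinesigram, BarycenterPoint,
    abdomen_load, barycenter, barycenter_inertia, build_statokinesigram,
    circling_count, detect_stance_epochs, laterality_index,
    max_lateral_deviation, mean_lateral_position, raw_inertia,
    raw_lateral_deviation, rearing_fraction,
)
from conftest import make_frame, make_frames


class TestBarycenter:
    def test_symmetric_loading_is_centered(self):
        xy = {"FL": (-1, -1), "FR": (-1, 1), "RL": (1, -1), "RR": (1, 1)}
        b = barycenter(make_frame(0.0, {p: 100.0 for p in PAWS}, xy=xy))
        assert b.Barx == pytest.approx(0.0)
        assert b.Bary == pytest.approx(0.0)

    def test_weighted_mean_worked_example(self):
        xy = {"FL": (0, 0), "FR": (2, 0), "RL": (0, 2), "RR": (2, 2)}
        b = barycenter(make_frame(0.0, {"FL": 1, "FR": 1, "RL": 1, "RR": 3}, xy=xy))
        assert b.Barx == pytest.approx(4 / 3)
        assert b.Bary == pytest.approx(4 / 3)

    def test_single_loaded_paw_degenerate(self):
        xy = {"FL": (0, 1), "FR": (5, 5), "RL": (-5, 5), "RR": (0, -9)}
        b = barycenter(make_frame(0.0, {"FL": 80, "FR": 0, "RL": 0, "RR": 0}, xy=xy))
        assert (b.Barx, b.Bary) == (0.0, 1.0)

    def test_zero_total_force_rejected(self):
        with pytest.raises(ValueError, match="total paw force"):
            barycenter(make_frame(0.0, {p: 0.0 for p in PAWS}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_barycenter_inside_convex_hull(self, seed):
        """Non-negative weights keep the barycenter inside the paw hull."""
        r = np.random.default_rng(seed)
        xy = {p: tuple(r.uniform(-10, 10, 2)) for p in PAWS}
        w = {p: r.uniform(0.1, 200) for p in PAWS}
        b = barycenter(make_frame(0.0, w, xy=xy))
        from scipy.spatial import Delaunay
        hull = Delaunay(np.array(list(xy.values())))
        assert hull.find_simplex([b.Barx, b.Bary - 1e-12]) >= 0 or \
            hull.find_simplex([b.Barx, b.Bary]) >= 0


class TestStanceEpochs:
    def test_constant_loading_single_epoch(self, steady_frames):
        epochs = detect_stance_epochs(steady_frames)
        assert len(epochs) == 1
        assert epochs[0].duration == pytest.approx(9.9)

    def test_rearing_segments_excluded(self):
        times = np.arange(0, 6.0, 0.1)
        weights = []
        for t in times:
            if 2.0 <= t < 4.0:   # rearing: front paws unloaded
                weights.append({"FL": 0, "FR": 0, "RL": 150, "RR": 150})
            else:
                weights.append({p: 75 for p in PAWS})
        epochs = detect_stance_epochs(make_frames(times, weights))
        assert len(epochs) == 2
        for e in epochs:
            arr = [e.frame.paws[p].w for p in PAWS]
            assert min(arr) >= 5.0

    def test_matches_brute_force_scan(self, rng):
        """Randomized loading: epochs equal an exhaustive frame-by-frame scan."""
        n = 400
        times = np.arange(n) * 0.1
        w = rng.uniform(0, 30, size=(n, 4))
        xy = np.tile([[4, -2], [4, 2], [-4, -2.5], [-4, 2.5]], (n, 1, 1))
        xy += rng.normal(0, 0.5, size=xy.shape)
        frames = [
            make_frame(times[i],
                       {p: w[i, j] for j, p in enumerate(PAWS)},
                       xy={p: tuple(xy[i, j]) for j, p in enumerate(PAWS)})
            for i in range(n)
        ]
        min_f, min_d, max_v = 5.0, 0.2, 2.0
        epochs = detect_stance_epochs(frames, min_f, min_d, max_v)

        # oracle: independent linear scan over frames
        def bary(i):
            tw = w[i].sum()
            return (xy[i, :, 0] * w[i]).sum() / tw, (xy[i, :, 1] * w[i]).sum() / tw

        expected = []
        i = 0
        while i < n:
            if not (w[i] >= min_f).all():
                i += 1
                continue
            j = i
            while j + 1 < n and (w[j + 1] >= min_f).all():
                (x0, y0), (x1, y1) = bary(j), bary(j + 1)
                if np.hypot(x1 - x0, y1 - y0) / (times[j + 1] - times[j]) > max_v:
                    break
                j += 1
            if times[j] - times[i] >= min_d:
                expected.append((times[i], times[j]))
            i = j + 1
        assert [(e.start_t, e.end_t) for e in epochs] == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_stance_epochs([])


class TestStatokinesigram:
    def _sk_from_points(self, pts_durs):
        pts = [BarycenterPoint(x, y, d) for (x, y), d in pts_durs]
        return Statokinesigram(pts, {p: np.zeros((len(pts), 2)) for p in PAWS})

    def test_two_identical_epochs_mean(self, steady_frames):
        epochs = detect_stance_epochs(steady_frames)
        sk = build_statokinesigram(epochs * 2)
        b = barycenter(epochs[0].frame)
        assert sk.weighted_mean == pytest.approx((b.Barx, b.Bary))

    def test_duration_weighted_mean(self):
        sk = self._sk_from_points([((0, 0), 1.0), ((1, 0), 3.0)])
        assert sk.weighted_mean == pytest.approx((0.75, 0.0))

    def test_shuffle_invariance(self, rng):
        pts = [((rng.normal(), rng.normal()), rng.uniform(0.2, 2)) for _ in range(9)]
        m1 = self._sk_from_points(pts).weighted_mean
        rng.shuffle(pts)
        m2 = self._sk_from_points(pts).weighted_mean
        assert m1 == pytest.approx(m2)

    def test_zero_epochs_distinct_error(self):
        with pytest.raises(ValueError, match="stance epochs"):
            build_statokinesigram([])

    def test_weighted_mean_matches_frame_level_computation(self, rng):
        """On a stance-only recording the epoch-level weighted mean equals a
        frame-level weighted barycenter mean within the epoch structure."""
        n = 300
        times = np.arange(n) * 0.1
        base = {p: 75.0 for p in PAWS}
        frames = make_frames(times, [
            {p: base[p] + rng.normal(0, 1) for p in PAWS} for _ in range(n)])
        epochs = detect_stance_epochs(frames, 5.0, 0.2, np.inf)
        assert len(epochs) == 1      # stance throughout
        sk = build_statokinesigram(epochs)
        frame_bary = np.array([[barycenter(f).Barx, barycenter(f).Bary]
                               for f in frames])
        # epoch representative = time-average frame; its barycenter is close to
        # (not exactly) the mean frame-level barycenter for small force noise
        np.testing.assert_allclose(sk.weighted_mean, frame_bary.mean(axis=0),
                                   atol=5e-3)


class TestDispersionMetrics:
    def _sk(self, ys, durs=None, xs=None):
        durs = durs or [1.0] * len(ys)
        xs = xs or [0.0] * len(ys)
        pts = [BarycenterPoint(x, y, d) for x, y, d in zip(xs, ys, durs)]
        return Statokinesigram(pts, {p: np.zeros((len(ys), 2)) for p in PAWS})

    def test_identical_points_zero_inertia(self):
        assert raw_inertia(self._sk([0.3] * 5)) == 0.0

    def test_unit_circle_inertia(self):
        th = np.linspace(0, 2 * np.pi, 37)[:-1]
        sk = self._sk(list(np.sin(th)), xs=list(np.cos(th)))
        assert raw_inertia(sk) == pytest.approx(1.0)

    def test_normalization_identity(self):
        sk = self._sk([0.1, -0.2, 0.4])
        assert barycenter_inertia(sk, sk) == pytest.approx(1.0)
        assert max_lateral_deviation(sk, sk) == pytest.approx(1.0)

    def test_lateral_deviation_span(self):
        assert raw_lateral_deviation(self._sk([-0.5, 0.1, 0.7])) == pytest.approx(1.2)
        assert raw_lateral_deviation(self._sk([0.2] * 4)) == 0.0

    def test_translation_invariance_and_scaling(self, rng):
        ys = list(rng.normal(size=8))
        xs = list(rng.normal(size=8))
        sk = self._sk(ys, xs=xs)
        shifted = self._sk([y + 3 for y in ys], xs=[x - 7 for x in xs])
        assert raw_inertia(shifted) == pytest.approx(raw_inertia(sk))
        doubled = self._sk([2 * y for y in ys], xs=[2 * x for x in xs])
        assert raw_inertia(doubled) == pytest.approx(4 * raw_inertia(sk))
        assert raw_lateral_deviation(doubled) == pytest.approx(
            2 * raw_lateral_deviation(sk))

    def test_mean_lateral_position_difference(self):
        post = self._sk([-0.8])
        pre = self._sk([-0.2])
        assert mean_lateral_position(post, pre) == pytest.approx(-0.6)
        assert mean_lateral_position(post, post) == pytest.approx(0.0)

    def test_missing_preop_warns_returns_nan(self):
        with pytest.warns(MissingBaselineWarning):
            assert np.isnan(mean_lateral_position(self._sk([0.0]), None))

    def test_degenerate_preop_inertia_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            barycenter_inertia(self._sk([0.1, 0.2]), self._sk([0.5] * 3))


class TestLateralityRearingAbdomen:
    def test_symmetric_loading_zero(self, steady_frames):
        assert laterality_index(steady_frames) == pytest.approx(0.0)

    def test_right_loaded(self):
        frames = make_frames([0.0, 0.1], [{"FL": 0, "RL": 0, "FR": 150, "RR": 150}] * 2)
        assert laterality_index(frames) == pytest.approx(300.0)

    def test_left_heavy_arithmetic(self):
        w = {"FR": 60, "RR": 60, "FL": 90, "RL": 90}
        frames = make_frames(np.arange(5) * 0.1, [w] * 5)
        assert laterality_index(frames) == pytest.approx(-60.0)

    def test_mirror_antisymmetry(self, rng):
        n = 50
        ws = [{p: rng.uniform(0, 100) for p in PAWS} for _ in range(n)]
        mirrored = [{"FL": w["FR"], "FR": w["FL"], "RL": w["RR"], "RR": w["RL"]}
                    for w in ws]
        times = np.arange(n) * 0.1
        assert laterality_index(make_frames(times, ws)) == pytest.approx(
            -laterality_index(make_frames(times, mirrored)))

    def test_rearing_never_and_quarter(self):
        times = np.arange(0, 8.0, 0.1)
        assert rearing_fraction(make_frames(times, [{p: 75 for p in PAWS}] * len(times))) == 0.0
        weights = [{"FL": 0, "FR": 0, "RL": 150, "RR": 150} if t < 2.0
                   else {p: 75 for p in PAWS} for t in times]
        assert rearing_fraction(make_frames(times, weights)) == pytest.approx(25.0)

    def test_abdomen_load_difference(self):
        times = np.arange(3) * 0.1
        post = make_frames(times, [{p: 75 for p in PAWS}] * 3, abdomen=[9.31] * 3)
        pre = make_frames(times, [{p: 75 for p in PAWS}] * 3, abdomen=[2.0] * 3)
        assert abdomen_load(post, pre) == pytest.approx(7.31)
        assert abdomen_load(post, post) == pytest.approx(0.0)
        zero = make_frames(times, [{p: 75 for p in PAWS}] * 3)
        assert abdomen_load(zero, pre) == pytest.approx(-2.0)
        with pytest.warns(MissingBaselineWarning):
            assert np.isnan(abdomen_load(post, None))


def _lap_trajectory(n_laps=3, speed=25.0, radius=8.0, dt=0.04, ccw=True,
                    lead_in=50):
    """Constructed heading ramp: straight lead-in then n full fast laps."""
    omega = (1 if ccw else -1) * speed / radius
    t_straight = dt * np.arange(lead_in)
    straight = np.column_stack([5 + speed * t_straight, np.full(lead_in, 40.0)])
    lap_t = np.arange(0, abs((n_laps * 2 * np.pi + 0.3) / omega), dt)
    th = omega * lap_t
    cx, cy = straight[-1]
    circle = np.column_stack([cx + radius * np.sin(np.abs(th)),
                              cy + (1 if ccw else -1) * radius * (1 - np.cos(np.abs(th)))])
    center = np.vstack([straight, circle[1:]])
    t = dt * np.arange(len(center))
    return TrackingTrajectory(t=t, nose=center + [1, 0], center=center,
                              tail=center - [1, 0], arena_size=(300.0, 300.0))


class TestCircling:
    def test_straight_path_no_laps(self):
        t = np.arange(100) * 0.04
        c = np.column_stack([5 + 20 * t, np.full(100, 40.0)])
        traj = TrackingTrajectory(t=t, nose=c + [1, 0], center=c, tail=c - [1, 0],
                                  arena_size=(300, 300))
        assert circling_count(traj, 10.0, "left") == 0

    def test_three_ccw_laps_counted_left(self):
        traj = _lap_trajectory(n_laps=3, ccw=True)
        assert circling_count(traj, 10.0, "left") == 3
        assert circling_count(traj, 10.0, "right") == 0

    def test_laps_below_speed_gate_ignored(self):
        traj = _lap_trajectory(n_laps=3, ccw=True, speed=25.0)
        assert circling_count(traj, min_speed=40.0, direction="left") == 0

    def test_mirror_equivalence(self):
        traj = _lap_trajectory(n_laps=2, ccw=True)
        mirrored = TrackingTrajectory(
            t=traj.t, nose=traj.nose * [1, -1], center=traj.center * [1, -1],
            tail=traj.tail * [1, -1], arena_size=(300, 300))
        assert circling_count(traj, 10.0, "left") == \
            circling_count(mirrored, 10.0, "right")

    def test_stationary_returns_zero(self):
        t = np.arange(10) * 0.04
        c = np.full((10, 2), 40.0)
        traj = TrackingTrajectory(t=t, nose=c + [1, 0], center=c, tail=c - [1, 0])
        assert circling_count(traj, 10.0, "left") == 0
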