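"""Dynamic-weight-bearing metrics: stance epochs, barycenter, statokinesigram,
dispersion statistics, laterality, rearing, abdomen load, circling.

The barycenter of a frame is the support-force-weighted mean of the four paw
positions

    Barx = (FLx·FLw + FRx·FRw + RLx·RLw + RRx·RRw) / (FLw + FRw + RLw + RRw)

and analogously for ``Bary``.  It is evaluated only over *stance epochs* —
maximal time intervals where the animal is static and bearing weight on all
four paws — and the statokinesigram is the sequence of per-epoch barycenter
points, summarized by a duration-weighted mean.

Normalization follows the acquisition protocol: the mean lateral position and
abdomen load are baseline-*subtracted* (preop value removed), while barycenter
inertia and maximum lateral deviation are baseline *ratios*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    FRONT_PAWS, HIND_PAWS, LEFT_PAWS, PAWS, RIGHT_PAWS,
    ForceFrame, PawState, TrackingTrajectory, frames_to_arrays,
)

__all__ = [
    "StanceEpoch", "BarycenterPoint", "Statokinesigram",
    "detect_stance_epochs", "barycenter", "build_statokinesigram",
    "mean_lateral_position", "barycenter_inertia", "max_lateral_deviation",
    "laterality_index", "rearing_fraction", "abdomen_load", "circling_count",
]


class MissingBaselineWarning(UserWarning):
    """A normalized metric could not be computed for lack of a preop baseline."""


@dataclass(frozen=True)
class BarycenterPoint:
    Barx: float
    Bary: float
    duration: float = 0.0


@dataclass(frozen=True)
class StanceEpoch:
    """A maximal static four-paw interval with its time-averaged frame."""

    start_t: float
    end_t: float
    frame: ForceFrame

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class Statokinesigram:
    """Barycenter trajectory over the stance epochs of one acquisition."""

    points: list[BarycenterPoint]
    paw_clouds: dict[str, np.ndarray]   # per paw: (n_epochs, 2) mean positions

    @property
    def durations(self) -> np.ndarray:
        return np.array([p.duration for p in self.points])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[p.Barx, p.Bary] for p in self.points])

    @property
    def weighted_mean(self) -> tuple[float, float]:
        """Duration-weighted mean barycenter (cm)."""
        d = self.durations
        xy = self.xy
        m = (xy * d[:, None]).sum(axis=0) / d.sum()
        return float(m[0]), float(m[1])

    @property
    def by_max(self) -> float:
        return float(max(p.Bary for p in self.points))

    @property
    def by_min(self) -> float:
        return float(min(p.Bary for p in self.points))


def barycenter(frame: ForceFrame) -> BarycenterPoint:
    """Support-force-weighted mean position of the four paws.

    Raises ``ValueError`` when the total paw force is zero (the barycenter is
    undefined for a fully unloaded platform).
    """
    w = np.array([frame.paws[p].w for p in PAWS])
    total = w.sum()
    if total <= 0:
        raise ValueError("barycenter undefined: total paw force is zero")
    x = np.array([frame.paws[p].x for p in PAWS])
    y = np.array([frame.paws[p].y for p in PAWS])
    return BarycenterPoint(float((x * w).sum() / total), float((y * w).sum() / total))


def _mean_frame(frames: Sequence[ForceFrame]) -> ForceFrame:
    """Arithmetic time-average of a run of frames (uniform weight per sample)."""
    arrays = frames_to_arrays(frames)
    x, y, w = arrays["x"].mean(axis=0), arrays["y"].mean(axis=0), arrays["w"].mean(axis=0)
    return ForceFrame(
        t=float(arrays["t"].mean()),
        paws={p: PawState(float(x[j]), float(y[j]), float(w[j])) for j, p in enumerate(PAWS)},
        abdomen_w=float(arrays["abdomen"].mean()),
    )


def detect_stance_epochs(
    frames: Sequence[ForceFrame],
    min_paw_force: float = 5.0,
    min_duration: float = 0.2,
    max_barycenter_speed: float = 2.0,
) -> list[StanceEpoch]:
    """Find maximal static four-paw intervals.

    A frame belongs to a stance run when all four paw forces are at least
    ``min_paw_force``; a run is split wherever the barycenter moves faster
    than ``max_barycenter_speed`` between consecutive frames; runs shorter
    than ``min_duration`` are discarded.  Epochs are returned time-ordered
    and disjoint, each carrying the time-averaged representative frame.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    if min_paw_force <= 0 or min_duration <= 0 or max_barycenter_speed <= 0:
        raise ValueError("thresholds must be positive")
    arrays = frames_to_arrays(frames)
    t, w = arrays["t"], arrays["w"]
    loaded = (w >= min_paw_force).all(axis=1)

    bx = np.full(len(t), np.nan)
    by = np.full(len(t), np.nan)
    total = w.sum(axis=1)
    ok = total > 0
    bx[ok] = (arrays["x"] * w).sum(axis=1)[ok] / total[ok]
    by[ok] = (arrays["y"] * w).sum(axis=1)[ok] / total[ok]

    epochs: list[StanceEpoch] = []
    i = 0
    n = len(t)
    while i < n:
        if not loaded[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and loaded[j + 1]:
            dt = t[j + 1] - t[j]
            speed = np.hypot(bx[j + 1] - bx[j], by[j + 1] - by[j]) / dt
            if speed > max_barycenter_speed:
                break
            j += 1
        if t[j] - t[i] >= min_duration:
            epochs.append(StanceEpoch(float(t[i]), float(t[j]), _mean_frame(frames[i : j + 1])))
        i = j + 1
    return epochs


def build_statokinesigram(epochs: Sequence[StanceEpoch]) -> Statokinesigram:
    """One barycenter point per epoch, weighted by epoch duration."""
    if len(epochs) == 0:
        raise ValueError("no stance epochs: cannot build a statokinesigram")
    points = []
    clouds = {p: [] for p in PAWS}
    for e in epochs:
        b = barycenter(e.frame)
        points.append(BarycenterPoint(b.Barx, b.Bary, e.duration))
        for p in PAWS:
            clouds[p].append([e.frame.paws[p].x, e.frame.paws[p].y])
    return Statokinesigram(points, {p: np.array(c) for p, c in clouds.items()})


def mean_lateral_position(
    sk: Statokinesigram, preop_sk: Statokinesigram | None
) -> float:
    """Duration-weighted mean ``Bary`` minus the preop value (cm; + = rightward).

    Returns NaN with a warning when the preop baseline is missing.
    """
    post = sk.weighted_mean[1]
    if preop_sk is None:
        warnings.warn("missing preop baseline for mean lateral position",
                      MissingBaselineWarning, stacklevel=2)
        return float("nan")
    return post - preop_sk.weighted_mean[1]


def raw_inertia(sk: Statokinesigram) -> float:
    """Duration-weighted mean squared distance from the weighted mean (cm²).

    This is the trace of the duration-weighted covariance of the barycenter
    cloud — the simplest rotation-invariant dispersion summary.
    """
    d = sk.durations
    xy = sk.xy
    mean = (xy * d[:, None]).sum(axis=0) / d.sum()
    return float((d * ((xy - mean) ** 2).sum(axis=1)).sum() / d.sum())


def barycenter_inertia(sk: Statokinesigram, preop_sk: Statokinesigram) -> float:
    """Dispersion of barycenter positions as a ratio to the preop dispersion."""
    base = raw_inertia(preop_sk)
    if base <= 0:
        raise ValueError("degenerate preop baseline: zero barycenter inertia")
    return raw_inertia(sk) / base


def raw_lateral_deviation(sk: Statokinesigram) -> float:
    """Lateral span By_max − By_min of the barycenter trace (cm, ≥ 0)."""
    return sk.by_max - sk.by_min


def max_lateral_deviation(sk: Statokinesigram, preop_sk: Statokinesigram) -> float:
    """Lateral instability as a ratio to the preop lateral span."""
    base = raw_lateral_deviation(preop_sk)
    if base <= 0:
        raise ValueError("degenerate preop baseline: zero lateral deviation")
    return raw_lateral_deviation(sk) / base


def _sample_weights(t: np.ndarray) -> np.ndarray:
    """Per-sample time weights: forward differences, last sample = median dt."""
    if len(t) == 1:
        return np.ones(1)
    dt = np.diff(t)
    return np.append(dt, np.median(dt))


def laterality_index(frames: Sequence[ForceFrame]) -> float:
    """Time-averaged right-minus-left supported weight (g; + = right-loaded)."""
    arrays = frames_to_arrays(frames)
    right = sum(arrays["w"][:, PAWS.index(p)] for p in RIGHT_PAWS)
    left = sum(arrays["w"][:, PAWS.index(p)] for p in LEFT_PAWS)
    wts = _sample_weights(arrays["t"])
    return float(np.average(right - left, weights=wts))


def rearing_fraction(frames: Sequence[ForceFrame], min_paw_force: float = 5.0) -> float:
    """Percent of recording time spent on the two hind paws only."""
    arrays = frames_to_arrays(frames)
    w = arrays["w"]
    front = np.column_stack([w[:, PAWS.index(p)] for p in FRONT_PAWS])
    hind = np.column_stack([w[:, PAWS.index(p)] for p in HIND_PAWS])
    rearing = (front < min_paw_force).all(axis=1) & (hind >= min_paw_force).all(axis=1)
    wts = _sample_weights(arrays["t"])
    return 100.0 * float(np.average(rearing.astype(float), weights=wts))


def abdomen_load(
    frames: Sequence[ForceFrame], preop_frames: Sequence[ForceFrame] | None
) -> float:
    """Time-averaged abdomen force minus the preop value (g; may be negative)."""
    arrays = frames_to_arrays(frames)
    post = float(np.average(arrays["abdomen"], weights=_sample_weights(arrays["t"])))
    if preop_frames is None:
        warnings.warn("missing preop baseline for abdomen load",
                      MissingBaselineWarning, stacklevel=2)
        return float("nan")
    pre_arrays = frames_to_arrays(preop_frames)
    pre = float(np.average(pre_arrays["abdomen"], weights=_sample_weights(pre_arrays["t"])))
    return post - pre


def circling_count(
    traj: TrackingTrajectory, min_speed: float = 18.0, direction: str = "left"
) -> int:
    """Number of completed fast 360° laps in the requested direction.

    The heading is taken from successive center-point displacements and
    unwrapped; a lap is counted each time the cumulative heading gains a full
    turn (relative to its running extremum) within a run where the
    instantaneous speed stays at or above ``min_speed``.  ``direction="left"``
    counts counter-clockwise turns (positive heading change), ``"right"``
    clockwise.  A stationary trajectory yields 0.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    t = traj.t
    c = traj.center
    valid = traj.valid
    # displacement steps between consecutive valid samples
    ok = valid[:-1] & valid[1:]
    dt = np.diff(t)
    dxy = np.diff(c, axis=0)
    speed = np.where(ok, np.hypot(dxy[:, 0], dxy[:, 1]) / dt, 0.0)
    moving = ok & (speed >= min_speed)
    heading = np.arctan2(dxy[:, 1], dxy[:, 0])

    sign = 1.0 if direction == "left" else -1.0
    total = 0
    i = 0
    n = len(moving)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and moving[j + 1]:
            j += 1
        if j > i:
            h = np.unwrap(heading[i : j + 1])
            net = sign * (h - h[0])
            # count full turns of progress beyond the running minimum
            run_min = 0.0
            progress_base = 0.0
            for v in net:
                run_min = min(run_min, v - progress_base)
                if v - progress_base - run_min >= 2 * np.pi:
                    total += 1
                    progress_base = v
                    run_min = 0.0
        i = j + 1
    return total
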