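"""Open-field locomotor and postural parameters.

From the tracked center point we derive the total distance moved (cm), the
mean velocity (cm/s) and the mean acceleration magnitude (cm/s²); from the
nose–center–tail triplet the mean body torsion (degrees, positive = bend
toward the animal's left, i.e. counter-clockwise seen from above).

Locomotor parameters are baseline-normalized as post/preop ratios; body
torsion as the post − preop difference, matching the acquisition protocol.

Positions are boxcar-smoothed (default 0.5 s) before differentiation: raw
finite differences on 25–30 Hz tracker output inflate the acceleration
estimate.  The window is configurable and can be set to 0 to disable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TrackingTrajectory

__all__ = ["KinematicsSummary", "path_metrics", "body_torsion", "normalize_kinematics"]


@dataclass(frozen=True)
class KinematicsSummary:
    total_distance: float       # cm
    mean_velocity: float        # cm/s
    mean_acceleration: float    # cm/s², mean magnitude
    mean_body_torsion: float    # degrees, + = leftward
    duration: float             # s


def _boxcar(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    out = np.empty_like(x)
    for col in range(x.shape[1]):
        # reflect-pad so the ends are not biased toward zero
        padded = np.pad(x[:, col], window // 2, mode="edge")
        out[:, col] = np.convolve(padded, kernel, mode="same")[window // 2 : window // 2 + len(x)]
    return out


def path_metrics(
    traj: TrackingTrajectory, smoothing_window: float = 0.5
) -> KinematicsSummary:
    """Distance, mean velocity and mean acceleration of the center point.

    Distance is the summed step length of the (optionally smoothed) path;
    mean velocity is distance over elapsed time; mean acceleration is the
    time-averaged magnitude of the second finite difference.  Masked samples
    are excluded.  Fewer than 2 valid samples is an error; acceleration needs
    at least 3 and is NaN otherwise.
    """
    t = traj.t[traj.valid]
    c = traj.center[traj.valid]
    if len(t) < 2:
        raise ValueError("need at least 2 valid samples for path metrics")
    if smoothing_window > 0:
        dt_med = float(np.median(np.diff(t)))
        win = max(1, int(round(smoothing_window / dt_med)))
        c = _boxcar(c.copy(), win)
    steps = np.diff(c, axis=0)
    dt = np.diff(t)
    distance = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    duration = float(t[-1] - t[0])
    vel_vec = steps / dt[:, None]           # at midpoints
    if len(t) >= 3:
        t_mid = (t[:-1] + t[1:]) / 2
        acc_vec = np.diff(vel_vec, axis=0) / np.diff(t_mid)[:, None]
        mean_acc = float(np.hypot(acc_vec[:, 0], acc_vec[:, 1]).mean())
    else:
        mean_acc = float("nan")
    torsion = body_torsion(traj)
    return KinematicsSummary(
        total_distance=distance,
        mean_velocity=distance / duration,
        mean_acceleration=mean_acc,
        mean_body_torsion=torsion,
        duration=duration,
    )


def body_torsion(traj: TrackingTrajectory) -> float:
    """Mean signed bend angle of the body axis (degrees, + = leftward).

    Per sample, the angle between the tail→center and center→nose vectors,
    measured counter-clockwise in the arena plane (seen from above a
    counter-clockwise nose deviation is a bend toward the animal's left).
    Samples with coincident points are skipped with a warning.
    """
    u = traj.center - traj.tail
    v = traj.nose - traj.center
    nu = np.hypot(u[:, 0], u[:, 1])
    nv = np.hypot(v[:, 0], v[:, 1])
    good = traj.valid & (nu > 1e-9) & (nv > 1e-9)
    if not np.all(good[traj.valid]):
        warnings.warn("skipping degenerate (coincident-point) samples in body torsion",
                      stacklevel=2)
    if not np.any(good):
        return float("nan")
    cross = u[good, 0] * v[good, 1] - u[good, 1] * v[good, 0]
    dot = (u[good] * v[good]).sum(axis=1)
    return float(np.degrees(np.arctan2(cross, dot)).mean())


def normalize_kinematics(
    post: KinematicsSummary, preop: KinematicsSummary
) -> dict[str, float]:
    """Baseline normalization: ratios for locomotion, difference for torsion."""
    out: dict[str, float] = {}
    for name in ("total_distance", "mean_velocity", "mean_acceleration"):
        base = getattr(preop, name)
        if base == 0 or not np.isfinite(base):
            warnings.warn(f"preop {name} is zero or undefined; ratio not computed",
                          stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = getattr(post, name) / base
    out["mean_body_torsion"] = post.mean_body_torsion - preop.mean_body_torsion
    return out
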