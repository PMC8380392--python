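"""Synthetic cohort generator.

Emulates the statistical structure of a unilateral-vestibular-neurectomy
(UVN) compensation experiment: three groups (sham, UVN + placebo, UVN + met)
followed from the pre-operative baseline to post-operative day 30.  A latent
syndrome intensity

    s(t) = s_inf + (s0 - s_inf) * exp(-lambda * t),   s(preop) = 0,

with group-specific peak ``s0``, recovery rate ``lambda`` (per day) and
residual plateau ``s_inf``, drives every modality monotonically:

* dynamic-weight-bearing force streams — leftward weight bias, abdomen
  contact, suppressed rearing and inflated barycenter dispersion all scale
  with s;
* open-field trajectories — leftward body torsion ∝ s, fast left circling
  bouts during the acute phase, velocity suppression early and lesion-linked
  hyperactivity late;
* landing paw quads — support surface inflated ∝ s;
* fluorescence micrographs — membrane-ring intensity and planted blob counts
  tied to group × time cellular targets;
* symptom checklists — thresholded on s.

The exponential family and all default magnitudes are generator conventions
chosen to land in the published ranges; they are emulation targets, not
estimates of the real data.  Generation is fully reproducible: every
animal × timepoint × modality draws from its own ``SeedSequence`` spawned
deterministically from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import (
    GROUPS, PAWS, TIMEPOINT_DAYS, TIMEPOINTS,
    AnimalRecord, ForceFrame, ImageGrid, PawState, TrackingTrajectory,
)
from .imaging import MembraneROISet, PawQuad
from .syndrome import SymptomChecklist

__all__ = [
    "GroupKinetics", "CohortConfig", "Cohort", "syndrome_intensity",
    "simulate_cohort", "fit_recovery_rate", "parameter_recovery_report",
    "recovery_study",
]


@dataclass(frozen=True)
class GroupKinetics:
    """Syndrome-kinetics parameters of one group."""

    s0: float        # peak intensity in [0, 1]
    lam: float       # recovery rate, per day
    s_inf: float     # residual plateau, <= s0

    def __post_init__(self) -> None:
        if not (0 <= self.s_inf <= self.s0 <= 1):
            raise ValueError("require 0 <= s_inf <= s0 <= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


#: Default kinetics: sham flat at zero; the treated (met) group peaks higher,
#: recovers more slowly and plateaus higher than placebo.
DEFAULT_KINETICS: dict[str, GroupKinetics] = {
    "sham": GroupKinetics(0.0, 0.0, 0.0),
    "UVN_placebo": GroupKinetics(0.75, 0.12, 0.10),
    "UVN_met": GroupKinetics(0.85, 0.05, 0.22),
}

#: Cellular targets (mean planted count, or ring intensity for the membrane
#: marker) per marker x group x sacrifice day.  Magnitudes follow the
#: published group means for the lesioned groups, with conventional sham
#: baselines.
DEFAULT_CELL_TARGETS: dict[str, dict[tuple[str, str], float]] = {
    "iba1": {("sham", "d3"): 8.0, ("sham", "d30"): 8.0,
             ("UVN_placebo", "d3"): 46.8, ("UVN_placebo", "d30"): 36.1,
             ("UVN_met", "d3"): 8.33, ("UVN_met", "d30"): 13.9},
    "gfap": {("sham", "d3"): 15.0, ("sham", "d30"): 15.0,
             ("UVN_placebo", "d3"): 49.6, ("UVN_placebo", "d30"): 34.1,
             ("UVN_met", "d3"): 16.1, ("UVN_met", "d30"): 16.0},
    "brdu": {("sham", "d3"): 1.5, ("sham", "d30"): 1.5,
             ("UVN_placebo", "d3"): 31.7, ("UVN_placebo", "d30"): 29.9,
             ("UVN_met", "d3"): 20.6, ("UVN_met", "d30"): 2.13},
    # percentage of marker cells with nuclear colocalization
    "gr_pct": {("sham", "d3"): 45.0, ("sham", "d30"): 45.0,
               ("UVN_placebo", "d3"): 65.3, ("UVN_placebo", "d30"): 60.0,
               ("UVN_met", "d3"): 44.8, ("UVN_met", "d30"): 45.0},
    # membrane-ring fluorescence above background threshold
    "kcc2": {("sham", "d3"): 40.0, ("sham", "d30"): 40.0,
             ("UVN_placebo", "d3"): 25.0, ("UVN_placebo", "d30"): 38.0,
             ("UVN_met", "d3"): 55.0, ("UVN_met", "d30"): 48.0},
}


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Acquisition durations default to the protocol lengths (5 min weight
    bearing, 10 min open field); analyses and tests use shorter recordings
    via ``scaled_down`` where full length adds nothing but runtime.
    """

    n_per_group: int = 20
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    kinetics: dict[str, GroupKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS))
    animal_re_sd: float = 0.06          # per-animal latent random effect
    # dynamic weight bearing
    dwb_duration: float = 300.0         # s
    dwb_rate: float = 10.0              # Hz
    body_weight_mean: float = 300.0     # g
    body_weight_sd: float = 15.0
    force_noise_sd: float = 3.0         # g per paw per frame
    lateral_bias_gain: float = 0.20     # left-fraction shift at s = 1
    abdomen_gain: float = 0.15          # fraction of body weight at s = 1
    dispersion_gain: float = 3.0        # epoch-to-epoch stance variability vs s
    # open field
    of_duration: float = 600.0          # s
    of_rate: float = 25.0               # Hz
    base_speed: float = 12.0            # cm/s
    torsion_gain: float = 15.0          # degrees at s = 1
    torsion_noise_sd: float = 3.0       # per-acquisition degrees
    torsion_sample_sd: float = 5.0      # per-sample tracker jitter, degrees
    circling_rate_acute: float = 9.0    # expected laps per acquisition at s = 1
    bout_speed: float = 22.0            # cm/s during circling bouts (fast laps)
    arena: tuple[float, float] = (80.0, 80.0)
    # tail suspension / support surface
    tst_trials: int = 10
    support_gain: float = 0.8           # area ratio excess at s = 1
    support_noise_sd: float = 0.08      # per-trial ratio noise
    # images
    image_size: int = 128
    bg_mean: float = 10.0
    bg_sd: float = 2.0
    n_rings: int = 6
    ring_intensity_sd: float = 3.0
    counting_frame_area: float = 425.10
    cells_per_group_per_day: int = 4    # sacrificed animals per group per day
    sections_mean: int = 10             # sections per animal (10 +/- 2)
    cell_targets: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CELL_TARGETS.items()})
    # checklist symptom thresholds on s
    symptom_thresholds: dict[str, float] = field(default_factory=lambda: {
        "head_tilt": 0.14, "bobbing": 0.30, "circling": 0.46,
        "retropulsion": 0.62, "tumbling": 0.78})
    symptom_noise_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g in self.groups:
            if g not in self.kinetics:
                raise ValueError(f"no kinetics for group {g!r}")
        unknown_tp = [t for t in self.timepoints if t not in TIMEPOINT_DAYS]
        if unknown_tp:
            raise ValueError(f"unknown timepoints {unknown_tp}")
        if self.dwb_duration <= 0 or self.of_duration <= 0:
            raise ValueError("durations must be positive")
        if self.animal_re_sd < 0 or self.force_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def scaled_down(self, dwb_duration: float = 60.0, of_duration: float = 60.0,
                    **overrides) -> "CohortConfig":
        """Copy with short acquisitions for simulation studies."""
        return replace(self, dwb_duration=dwb_duration, of_duration=of_duration,
                       **overrides)


def syndrome_intensity(day: float, kin: GroupKinetics) -> float:
    """Latent syndrome intensity in [0, 1] at post-operative ``day``.

    Zero pre-operatively (day 0) and for an unlesioned group; exponential
    recovery toward the plateau otherwise.
    """
    if day <= 0 or kin.s0 == 0:
        return 0.0
    return kin.s_inf + (kin.s0 - kin.s_inf) * math.exp(-kin.lam * day)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# stable per-modality stream indices for seeding
_MOD = {"latent": 0, "dwb": 1, "openfield": 2, "tst": 3, "checklist": 4, "cells": 5}


def _simulate_dwb(s: float, weight: float, cfg: CohortConfig,
                  rng: np.random.Generator) -> list[ForceFrame]:
    """Segment-based force stream: stance / rearing / locomotion episodes."""
    dt = 1.0 / cfg.dwb_rate
    n_total = int(round(cfg.dwb_duration * cfg.dwb_rate))
    # target *time* shares: rearing collapses with the syndrome (sham ~50%)
    share_rear = 0.5 * (1.0 - s)
    share_move = 0.15 + 0.10 * s
    share_stance = 1.0 - share_rear - share_move
    durs = np.array([2.5, 1.2, 1.5])   # mean episode length per state, s
    p = np.array([share_stance, share_rear, share_move]) / durs
    p = p / p.sum()                    # episode-type probability from time share
    template = np.array([[4.0, -2.0], [4.0, 2.0], [-4.0, -2.5], [-4.0, 2.5]])

    t_list, x_list, y_list, w_list, a_list = [], [], [], [], []
    t0 = 0.0
    n_done = 0
    while n_done < n_total:
        state = rng.choice(3, p=p)
        mean_dur = durs[state]
        n = max(2, int(round(rng.exponential(mean_dur) / dt)))
        n = min(n, n_total - n_done)
        if n < 2:
            n = n_total - n_done
        t = t0 + dt * np.arange(n)
        jitter = rng.normal(0.0, 0.3 + 0.1 * cfg.dispersion_gain * s, size=(1, 4, 2))
        pos = template[None, :, :] + jitter                      # per-episode stance
        pos = np.broadcast_to(pos, (n, 4, 2)).copy()
        if state == 2:  # locomotion: platform-frame paw positions drift fast
            drift = rng.normal(0.0, 1.0, size=2)
            drift = 6.0 * drift / max(np.hypot(*drift), 1e-9)    # cm/s
            pos += (dt * np.arange(n))[:, None, None] * drift[None, None, :]
        left_frac = 0.5 + cfg.lateral_bias_gain * s + rng.normal(0.0, 0.02 * (1 + 2 * s))
        left_frac = float(np.clip(left_frac, 0.05, 0.95))
        front_frac = 0.40
        if state == 1:  # rearing: front paws unloaded
            base = weight * np.array([0.0, 0.0, left_frac, 1 - left_frac])
            w = base[None, :] + rng.uniform(0.0, 2.0, size=(n, 4)) * np.array([1, 1, 0, 0])
            w[:, 2:] += rng.normal(0.0, cfg.force_noise_sd, size=(n, 2))
        else:
            base = weight * np.array([
                front_frac * left_frac, front_frac * (1 - left_frac),
                (1 - front_frac) * left_frac, (1 - front_frac) * (1 - left_frac)])
            w = base[None, :] + rng.normal(0.0, cfg.force_noise_sd, size=(n, 4))
        w = np.clip(w, 0.0, None)
        abdomen = np.zeros(n)
        if state == 0 and s > 0 and rng.random() < 0.8 * s:
            abdomen = np.clip(
                weight * cfg.abdomen_gain + rng.normal(0, 2.0, size=n), 0.0, None)
        t_list.append(t); x_list.append(pos[:, :, 0]); y_list.append(pos[:, :, 1])
        w_list.append(w); a_list.append(abdomen)
        t0 = t[-1] + dt
        n_done += n

    t = np.concatenate(t_list)
    x = np.vstack(x_list); y = np.vstack(y_list)
    w = np.vstack(w_list); abdomen = np.concatenate(a_list)
    return [
        ForceFrame(
            t=float(t[i]),
            paws={p: PawState(float(x[i, j]), float(y[i, j]), float(w[i, j]))
                  for j, p in enumerate(PAWS)},
            abdomen_w=float(abdomen[i]),
        )
        for i in range(len(t))
    ]


def _simulate_trajectory(s: float, day: float, lesioned: bool, cfg: CohortConfig,
                         rng: np.random.Generator) -> TrackingTrajectory:
    dt = 1.0 / cfg.of_rate
    n = int(round(cfg.of_duration * cfg.of_rate))
    w, h = cfg.arena

    speed = cfg.base_speed * (1.0 - 0.6 * s)
    if lesioned:  # late locomotor hyperactivity after the acute phase
        speed *= 1.0 + 0.5 * (1.0 - math.exp(-max(0.0, day - 3.0) / 10.0))
    speed = max(speed, 1.0)

    # circling bouts: fast full left laps, essentially acute-phase only
    rate = cfg.circling_rate_acute * s if 0 < day <= 3 else 0.5 * s
    n_bouts = rng.poisson(rate)
    bout_speed = max(cfg.bout_speed, speed + 4.0)
    bout_radius = 8.0
    bout_len = int(round(2 * math.pi * bout_radius / bout_speed / dt)) + 2
    starts = np.sort(rng.choice(max(1, n - bout_len - 1), size=min(n_bouts, 50),
                                replace=False)) if n_bouts else np.array([], dtype=int)
    # drop overlapping bouts
    keep = []
    last_end = -1
    for st in starts:
        if st > last_end:
            keep.append(int(st))
            last_end = st + bout_len
    in_bout = np.zeros(n, dtype=bool)
    for st in keep:
        in_bout[st: st + bout_len] = True

    heading = np.empty(n)
    heading[0] = rng.uniform(0, 2 * math.pi)
    turn_noise = rng.normal(0.0, 1.2 * math.sqrt(dt), size=n)
    omega_bout = bout_speed / bout_radius          # rad/s, CCW (leftward)
    center = np.empty((n, 2))
    center[0] = (w / 2, h / 2)
    spd = np.where(in_bout, bout_speed, speed)
    for i in range(1, n):
        dh = omega_bout * dt if in_bout[i] else turn_noise[i]
        heading[i] = heading[i - 1] + dh
        step = spd[i] * dt
        nxt = center[i - 1] + step * np.array([math.cos(heading[i]), math.sin(heading[i])])
        # reflect at the walls
        for k, lim in enumerate((w, h)):
            if nxt[k] < 1.0 or nxt[k] > lim - 1.0:
                heading[i] = math.pi - heading[i] if k == 0 else -heading[i]
                nxt[k] = np.clip(nxt[k], 1.0, lim - 1.0)
        center[i] = nxt

    body = 18.0
    torsion = math.radians(
        cfg.torsion_gain * s + rng.normal(0.0, cfg.torsion_noise_sd))
    tors = torsion + np.radians(rng.normal(0.0, cfg.torsion_sample_sd, size=n))
    hvec = np.column_stack([np.cos(heading), np.sin(heading)])
    nose_dir = np.column_stack([np.cos(heading + tors), np.sin(heading + tors)])
    tail = center - (body / 2) * hvec
    nose = center + (body / 2) * nose_dir
    t = dt * np.arange(n)
    return TrackingTrajectory(t=t, nose=nose, center=center, tail=tail,
                              arena_size=cfg.arena)


def _simulate_paw_quads(s: float, cfg: CohortConfig,
                        rng: np.random.Generator) -> list[PawQuad]:
    """Landing paw quads whose expected area ratio to baseline is 1 + gain·s."""
    quads = []
    half_l, half_w = 4.0, 3.0   # base stance: 8 x 6 cm rectangle
    for _ in range(cfg.tst_trials):
        ratio = max(0.3, 1.0 + cfg.support_gain * s
                    + rng.normal(0.0, cfg.support_noise_sd))
        scale = math.sqrt(ratio)
        jit = rng.normal(0.0, 0.15, size=(4, 2))
        pts = scale * np.array([
            [half_l, -half_w], [half_l, half_w],
            [-half_l, -half_w], [-half_l, half_w]]) + jit
        quads.append(PawQuad(FL=tuple(pts[0]), FR=tuple(pts[1]),
                             RL=tuple(pts[2]), RR=tuple(pts[3])))
    return quads


def _simulate_checklist(s: float, cfg: CohortConfig,
                        rng: np.random.Generator) -> SymptomChecklist:
    flags = {
        sym: bool(s + rng.normal(0.0, cfg.symptom_noise_sd) > thr)
        for sym, thr in cfg.symptom_thresholds.items()
    }
    return SymptomChecklist(**flags)


def _place_blobs(n_blobs: int, lo: int, hi: int, min_sep: float,
                 rng: np.random.Generator, max_tries: int = 30000) -> np.ndarray:
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_blobs and tries < max_tries:
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
        tries += 1
    return np.array(pts).reshape(-1, 2)


def simulate_blob_image(n_blobs: int, cfg: CohortConfig,
                        rng: np.random.Generator) -> tuple[ImageGrid, np.ndarray]:
    """Punctate-staining image with ``n_blobs`` planted cells inside the frame.

    Returns the image and the true centroids (row, col, px).  Pixel size is
    chosen so the counting frame (area ``counting_frame_area``) spans the
    central region of the image.
    """
    size = cfg.image_size
    side_px = int(size * 0.85)
    pixel_size = math.sqrt(cfg.counting_frame_area) / side_px
    img = np.clip(rng.normal(cfg.bg_mean, cfg.bg_sd, size=(size, size)), 0, None)
    margin = (size - side_px) // 2
    cents = _place_blobs(n_blobs, margin + 5, margin + side_px - 5, 10.0, rng)
    yy, xx = np.mgrid[0:size, 0:size]
    for (r, c) in cents:
        amp = 120.0 + rng.normal(0, 10)
        img += amp * np.exp(-(((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5 ** 2)))
    grid = ImageGrid(np.clip(img, 0, 65535).astype(np.uint16),
                     pixel_size=pixel_size, pixel_unit="um")
    return grid, cents


def simulate_ring_image(
    ring_intensity: float, cfg: CohortConfig, rng: np.random.Generator,
) -> tuple[ImageGrid, MembraneROISet, list[float]]:
    """Membrane-staining image: annular rings on a noisy dim background.

    Returns the image, an ROI set (one dilated annulus per ring plus a
    neuron-free background polygon) and the true per-ring intensities.
    """
    size = cfg.image_size
    img = np.clip(rng.normal(cfg.bg_mean, cfg.bg_sd, size=(size, size)), 0, None)
    centers = _place_blobs(cfg.n_rings, 30, size - 8, 24.0, rng)
    yy, xx = np.mgrid[0:size, 0:size]
    rois: list[np.ndarray] = []
    truths: list[float] = []
    r_in, r_out = 7.0, 10.0
    for (r, c) in centers:
        dist = np.hypot(yy - r, xx - c)
        ring = (dist >= r_in) & (dist < r_out)
        inten = max(0.0, ring_intensity + rng.normal(0.0, cfg.ring_intensity_sd))
        img[ring] = inten + rng.normal(0.0, 1.0, size=int(ring.sum()))
        roi = np.argwhere((dist >= r_in - 2) & (dist < r_out + 2))
        rois.append(roi)
        truths.append(inten)
    # background strip devoid of rings: top-left corner margin
    bg = np.argwhere((yy < 22) & (xx < 22))
    rois_set = MembraneROISet(background=bg, membranes=rois)
    grid = ImageGrid(np.clip(img, 0, 65535).astype(np.uint16),
                     pixel_size=1.0, pixel_unit="um")
    return grid, rois_set, truths


@dataclass
class Cohort:
    """In-memory synthetic dataset keyed by (animal_id, timepoint)."""

    config: CohortConfig
    records: dict[tuple[str, str], AnimalRecord]
    latent: pd.DataFrame     # animal_id, group, timepoint, day, s

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs, in generation order."""
        seen: dict[str, str] = {}
        for (aid, _tp), rec in self.records.items():
            seen.setdefault(aid, rec.group)
        return list(seen.items())

    def get(self, animal_id: str, timepoint: str) -> AnimalRecord:
        return self.records[(animal_id, timepoint)]


def simulate_cohort(
    config: CohortConfig,
    modalities: Sequence[str] = ("dwb", "openfield", "tst", "checklist", "cells"),
) -> Cohort:
    """Generate a full synthetic cohort (deterministic in ``config.seed``).

    ``modalities`` restricts generation (e.g. ``("openfield",)`` for cheap
    simulation studies).  Cellular images are produced only for the sacrifice
    subset: ``cells_per_group_per_day`` animals per group at d3 and d30,
    ~10 sections each, mirroring the terminal design of the study.
    """
    config.validate()
    unknown = set(modalities) - {"dwb", "openfield", "tst", "checklist", "cells"}
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    records: dict[tuple[str, str], AnimalRecord] = {}
    latent_rows = []
    for gi, group in enumerate(config.groups):
        kin = config.kinetics[group]
        lesioned = kin.s0 > 0
        for ai in range(config.n_per_group):
            aid = f"{group}_{ai:02d}"
            lrng = _rng(config.seed, _MOD["latent"], gi, ai)
            u = lrng.normal(0.0, config.animal_re_sd)
            weight = lrng.normal(config.body_weight_mean, config.body_weight_sd)
            for ti, tp in enumerate(config.timepoints):
                day = TIMEPOINT_DAYS[tp]
                s = 0.0 if day <= 0 else float(
                    np.clip(syndrome_intensity(day, kin) + u, 0.0, 1.0))
                latent_rows.append({"animal_id": aid, "group": group,
                                    "timepoint": tp, "day": day, "s": s})
                payload: dict = {}
                if "dwb" in modalities:
                    payload["force_frames"] = _simulate_dwb(
                        s, weight, config, _rng(config.seed, _MOD["dwb"], gi, ai, ti))
                if "openfield" in modalities:
                    payload["trajectory"] = _simulate_trajectory(
                        s, day, lesioned, config,
                        _rng(config.seed, _MOD["openfield"], gi, ai, ti))
                if "tst" in modalities and (day <= 0 or day >= 3):
                    payload["paw_quads"] = _simulate_paw_quads(
                        s, config, _rng(config.seed, _MOD["tst"], gi, ai, ti))
                if "checklist" in modalities:
                    payload["checklist"] = _simulate_checklist(
                        s, config, _rng(config.seed, _MOD["checklist"], gi, ai, ti))
                records[(aid, tp)] = AnimalRecord(aid, group, tp, payload)
            if "cells" in modalities and ai < 2 * config.cells_per_group_per_day:
                # first half of the subset sacrificed at d3, second at d30
                sac_tp = "d3" if ai < config.cells_per_group_per_day else "d30"
                crng = _rng(config.seed, _MOD["cells"], gi, ai)
                records[(aid, sac_tp)].payload["cells"] = _simulate_cell_sections(
                    group, sac_tp, config, crng)
    return Cohort(config, records, pd.DataFrame(latent_rows))


def _simulate_cell_sections(group: str, tp: str, cfg: CohortConfig,
                            rng: np.random.Generator) -> dict:
    """Per-animal image sections for each cellular marker."""
    n_sections = int(np.clip(round(rng.normal(cfg.sections_mean, 1.0)), 8, 12))
    out: dict = {"n_sections": n_sections}
    for marker in ("iba1", "gfap", "brdu"):
        target = cfg.cell_targets[marker][(group, tp)]
        sections = []
        for _ in range(n_sections):
            n_true = int(rng.poisson(target))
            img, cents = simulate_blob_image(n_true, cfg, rng)
            sections.append({"image": img, "true_centroids": cents, "n_true": n_true})
        out[marker] = sections
    # GR: marker blobs plus a nuclear channel colocalized for target percent
    pct = cfg.cell_targets["gr_pct"][(group, tp)]
    gr_sections = []
    for _ in range(n_sections):
        n_gr = int(rng.poisson(30))
        img, cents = simulate_blob_image(n_gr, cfg, rng)
        n_coloc = int(round(n_gr * pct / 100.0))
        order = rng.permutation(len(cents))
        nuc = cents[order[:n_coloc]] + rng.normal(0, 0.5, size=(n_coloc, 2))
        gr_sections.append({"image": img, "true_centroids": cents,
                            "nuclear_centroids": nuc, "n_true": n_gr})
    out["gr"] = gr_sections
    # KCC2: membrane rings
    target = cfg.cell_targets["kcc2"][(group, tp)]
    kcc2_sections = []
    for _ in range(n_sections):
        img, rois, truths = simulate_ring_image(target, cfg, rng)
        kcc2_sections.append({"image": img, "rois": rois, "true_intensities": truths})
    out["kcc2"] = kcc2_sections
    return out


# ---------------------------------------------------------------------------
# parameter recovery

def _decay(t: np.ndarray, a: float, b: float, lam: float) -> np.ndarray:
    return a + b * np.exp(-lam * t)


def fit_recovery_rate(days: np.ndarray, values: np.ndarray) -> dict[str, float]:
    """Nonlinear least-squares fit of a + b·exp(−λ·t) to post-operative means.

    Returns the fitted plateau, amplitude and recovery rate λ (per day).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(days) < 4:
        raise ValueError("need at least 4 post-operative timepoints")
    order = np.argsort(days)
    days, values = days[order], values[order]
    span = float(np.ptp(values))
    if span == 0:
        return {"plateau": float(values[0]), "amplitude": 0.0, "lam": 0.0}
    lo, hi = float(values.min()), float(values.max())
    # plateau and amplitude bounds block the near-linear lam -> 0 degeneracy
    bounds = ([lo - span, 0.0, 1e-3], [hi + span, 10.0 * span, 3.0])
    best = None
    for lam0 in (0.03, 0.1, 0.3):
        try:
            popt, _ = curve_fit(_decay, days, values,
                                p0=[lo, span, lam0], maxfev=20000, bounds=bounds)
        except RuntimeError:
            continue
        sse = float(((values - _decay(days, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("exponential recovery fit failed to converge")
    popt = best[1]
    return {"plateau": float(popt[0]), "amplitude": float(popt[1]),
            "lam": float(popt[2])}


def fit_shared_recovery_rate(
    curves: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]],
) -> dict[str, float]:
    """Joint exponential fit with one shared λ across several time courses.

    ``curves`` is a list of (days, group-mean values, SEMs or None); each
    curve gets its own plateau and amplitude, all share the recovery rate.
    Residuals are inverse-SEM weighted (falling back to the curve span when
    SEMs are unavailable), so precisely measured metrics dominate the pooled
    λ estimate.
    """
    from scipy.optimize import least_squares

    if not curves:
        raise ValueError("no time courses to fit")
    spans = [max(float(np.ptp(v)), 1e-12) for _, v, _ in curves]
    weights = []
    for (t, v, sem), span in zip(curves, spans):
        if sem is not None and np.all(np.isfinite(sem)) and np.all(sem > 0):
            weights.append(1.0 / np.asarray(sem, float))
        else:
            weights.append(np.full(len(v), 1.0 / span))

    def residuals(theta: np.ndarray) -> np.ndarray:
        lam = theta[0]
        res = []
        for m, (t, v, _) in enumerate(curves):
            a, b = theta[1 + 2 * m], theta[2 + 2 * m]
            res.append(weights[m] * (v - _decay(np.asarray(t, float), a, b, lam)))
        return np.concatenate(res)

    best = None
    for lam0 in (0.03, 0.1, 0.3):
        x0 = [lam0]
        lo, hi = [1e-3], [3.0]
        for (t, v, _), span in zip(curves, spans):
            x0 += [float(np.min(v)), span]
            lo += [float(np.min(v)) - span, 0.0]
            hi += [float(np.max(v)) + span, 10.0 * span]
        sol = least_squares(residuals, x0=x0, bounds=(lo, hi), max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    return {"lam": float(best.x[0]), "cost": float(best.cost)}


#: Baseline-normalized metrics pooled for recovery-rate estimation.
RECOVERY_METRICS: tuple[str, ...] = ("mean_body_torsion", "support_surface")


def parameter_recovery_report(
    config: CohortConfig, metrics: pd.DataFrame,
    metric_names: Sequence[str] = RECOVERY_METRICS,
) -> pd.DataFrame:
    """Compare generator recovery rates with rates re-fit from pipeline output.

    ``metrics`` is a tidy table (animal_id, group, timepoint, metric, value)
    of baseline-normalized values; for each lesioned group the post-operative
    group-mean time courses of the requested metrics are jointly fit with an
    exponential decay sharing one λ, which is compared with the generator's.
    """
    rows = []
    for group in config.groups:
        kin = config.kinetics[group]
        if kin.s0 == 0:
            continue
        curves = []
        used = []
        for metric in metric_names:
            g = metrics[(metrics["metric"] == metric) & (metrics["group"] == group)]
            if not len(g):
                continue
            agg = g.groupby("timepoint")["value"].agg(["mean", "sem"])
            days = np.array([TIMEPOINT_DAYS[tp] for tp in agg.index])
            post = days > 0
            if post.sum() >= 4:
                curves.append((days[post], agg["mean"].to_numpy()[post],
                               agg["sem"].to_numpy()[post]))
                used.append(metric)
        if not curves:
            continue
        fit = fit_shared_recovery_rate(curves)
        rows.append({
            "group": group, "metrics": "+".join(used),
            "lam_true": kin.lam, "lam_est": fit["lam"],
            "rel_error": (fit["lam"] - kin.lam) / kin.lam,
        })
    return pd.DataFrame(rows)


def recovery_study(
    config: CohortConfig, n_replicates: int = 50, seed: int = 0,
    metric_names: Sequence[str] = RECOVERY_METRICS,
) -> pd.DataFrame:
    """Replicate cohorts, re-estimate λ per group, report bias and RMSE.

    Generates only the modalities the fit metrics need (open field and tail
    suspension), so each replicate is cheap; RMSE is expressed relative to
    the true λ.
    """
    from .pipeline import openfield_metrics, tst_metrics  # avoid an import cycle

    results: list[pd.DataFrame] = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=seed + rep)
        cohort = simulate_cohort(cfg, modalities=("openfield", "tst"))
        metrics = pd.concat([openfield_metrics(cohort), tst_metrics(cohort)],
                            ignore_index=True)
        rep_df = parameter_recovery_report(cfg, metrics, metric_names=metric_names)
        rep_df["replicate"] = rep
        results.append(rep_df)
    all_df = pd.concat(results, ignore_index=True)
    out = []
    for group, g in all_df.groupby("group"):
        lam_true = g["lam_true"].iloc[0]
        err = g["lam_est"] - lam_true
        out.append({
            "group": group, "lam_true": lam_true,
            "lam_est_mean": float(g["lam_est"].mean()),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err ** 2).mean())),
            "rmse_relative": float(np.sqrt((err ** 2).mean()) / lam_true),
            "n_replicates": len(g),
        })
    return pd.DataFrame(out)
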