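"""Shared data model and file I/O for the quantification pipeline.

Coordinate and unit conventions, fixed package-wide:

* x — antero-posterior axis, in cm, positive toward the head (statokinesigram
  abscissa);
* y — lateral axis, in cm, positive toward the animal's *right*, so that a
  positive lateral barycenter position or laterality index means a rightward
  weight shift;
* forces in grams, times in seconds, angles in degrees.

All readers validate their input and raise ``ValueError`` with the offending
CSV line number; invalid data never propagates silently into the metric
modules.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("vestcomp")

#: Paw labels in canonical order: front-left, front-right, rear-left, rear-right.
PAWS: tuple[str, ...] = ("FL", "FR", "RL", "RR")
FRONT_PAWS: tuple[str, ...] = ("FL", "FR")
HIND_PAWS: tuple[str, ...] = ("RL", "RR")
LEFT_PAWS: tuple[str, ...] = ("FL", "RL")
RIGHT_PAWS: tuple[str, ...] = ("FR", "RR")

GROUPS: tuple[str, ...] = ("sham", "UVN_placebo", "UVN_met")
TIMEPOINTS: tuple[str, ...] = ("preop", "d1", "d2", "d3", "d7", "d14", "d21", "d30")
#: Post-operative day for each timepoint label (preop mapped to day 0).
TIMEPOINT_DAYS: dict[str, float] = {
    "preop": 0.0, "d1": 1.0, "d2": 2.0, "d3": 3.0,
    "d7": 7.0, "d14": 14.0, "d21": 21.0, "d30": 30.0,
}


@dataclass(frozen=True)
class PawState:
    """Position (cm) and support force (g) of one paw at one sample."""

    x: float
    y: float
    w: float


@dataclass(frozen=True)
class ForceFrame:
    """One dynamic-weight-bearing sample: four paw states plus abdomen force."""

    t: float
    paws: Mapping[str, PawState]
    abdomen_w: float = 0.0

    def __post_init__(self) -> None:
        missing = [p for p in PAWS if p not in self.paws]
        if missing:
            raise ValueError(f"ForceFrame missing paws: {missing}")

    @property
    def total_paw_force(self) -> float:
        return float(sum(self.paws[p].w for p in PAWS))

    def is_rearing(self, min_paw_force: float) -> bool:
        """Standing on the two hind paws only (front forces below threshold)."""
        return (
            all(self.paws[p].w < min_paw_force for p in FRONT_PAWS)
            and all(self.paws[p].w >= min_paw_force for p in HIND_PAWS)
        )


def frames_to_arrays(frames: Sequence[ForceFrame]) -> dict[str, np.ndarray]:
    """Vectorize a frame sequence: t (N,), x/y/w (N,4 in PAWS order), abdomen (N,)."""
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    t = np.array([f.t for f in frames], dtype=float)
    x = np.array([[f.paws[p].x for p in PAWS] for f in frames], dtype=float)
    y = np.array([[f.paws[p].y for p in PAWS] for f in frames], dtype=float)
    w = np.array([[f.paws[p].w for p in PAWS] for f in frames], dtype=float)
    abdomen = np.array([f.abdomen_w for f in frames], dtype=float)
    return {"t": t, "x": x, "y": y, "w": w, "abdomen": abdomen}


def frames_from_arrays(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray,
    abdomen: np.ndarray | None = None,
) -> list[ForceFrame]:
    if abdomen is None:
        abdomen = np.zeros_like(np.asarray(t, dtype=float))
    return [
        ForceFrame(
            t=float(t[i]),
            paws={p: PawState(float(x[i, j]), float(y[i, j]), float(w[i, j]))
                  for j, p in enumerate(PAWS)},
            abdomen_w=float(abdomen[i]),
        )
        for i in range(len(t))
    ]


#: Default column dialect for dynamic-weight-bearing CSV exports.
DEFAULT_DWB_DIALECT: dict[str, str] = {"t": "t", "abdomen_w": "abdomen_w"}
for _p in PAWS:
    for _c in ("x", "y", "w"):
        DEFAULT_DWB_DIALECT[f"{_p}{_c}"] = f"{_p}{_c}"


def read_force_frames(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[ForceFrame]:
    """Read a per-sample force table into validated :class:`ForceFrame` objects.

    ``dialect`` maps canonical field names (``t``, ``FLx`` … ``RRw``,
    ``abdomen_w``) to the column names of the device export.  Forces must be
    non-negative, coordinates finite and timestamps strictly increasing;
    violations raise ``ValueError`` naming the CSV line (header = line 1).
    """
    dialect = dict(DEFAULT_DWB_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    def col(name: str) -> np.ndarray:
        return df[dialect[name]].to_numpy(dtype=float)

    t = col("t")
    if np.any(~np.isfinite(t)):
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise ValueError(f"{path}: non-finite timestamp at line {row + 2}")
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotone timestamps at line {row + 2}")
    x = np.column_stack([col(f"{p}x") for p in PAWS])
    y = np.column_stack([col(f"{p}y") for p in PAWS])
    w = np.column_stack([col(f"{p}w") for p in PAWS])
    abdomen = col("abdomen_w")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        bad = ~(np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1))
        raise ValueError(
            f"{path}: non-finite paw coordinate at line {int(np.flatnonzero(bad)[0]) + 2}"
        )
    neg = (w < 0).any(axis=1) | (abdomen < 0)
    if np.any(neg):
        raise ValueError(
            f"{path}: negative force at line {int(np.flatnonzero(neg)[0]) + 2}"
        )
    return frames_from_arrays(t, x, y, w, abdomen)


def write_force_frames(
    frames: Sequence[ForceFrame], path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    dialect = dict(DEFAULT_DWB_DIALECT if dialect is None else dialect)
    arrays = frames_to_arrays(frames)
    data = {dialect["t"]: arrays["t"]}
    for j, p in enumerate(PAWS):
        data[dialect[f"{p}x"]] = arrays["x"][:, j]
        data[dialect[f"{p}y"]] = arrays["y"][:, j]
        data[dialect[f"{p}w"]] = arrays["w"][:, j]
    data[dialect["abdomen_w"]] = arrays["abdomen"]
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class TrackingTrajectory:
    """Timestamped nose/center/tail path in the arena frame (cm).

    Samples with any non-finite coordinate are kept but masked
    (``valid[i] = False``) so gaps stay visible to downstream metrics.
    """

    t: np.ndarray            # (N,)
    nose: np.ndarray         # (N, 2)
    center: np.ndarray       # (N, 2)
    tail: np.ndarray         # (N, 2)
    arena_size: tuple[float, float] = (80.0, 80.0)
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.nose = np.asarray(self.nose, dtype=float).reshape(-1, 2)
        self.center = np.asarray(self.center, dtype=float).reshape(-1, 2)
        self.tail = np.asarray(self.tail, dtype=float).reshape(-1, 2)
        n = len(self.t)
        if n < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.nose.shape[0] != n or self.center.shape[0] != n or self.tail.shape[0] != n:
            raise ValueError("coordinate arrays must match timestamp length")
        if np.any(~np.isfinite(self.t)) or np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be finite and strictly increasing")
        if self.valid is None:
            coords = np.hstack([self.nose, self.center, self.tail])
            self.valid = np.isfinite(coords).all(axis=1)
        self.valid = np.asarray(self.valid, dtype=bool)
        self._check_bounds()

    def _check_bounds(self, tol: float = 5.0) -> None:
        w, h = self.arena_size
        pts = self.center[self.valid]
        if pts.size and (
            np.any(pts[:, 0] < -tol) or np.any(pts[:, 0] > w + tol)
            or np.any(pts[:, 1] < -tol) or np.any(pts[:, 1] > h + tol)
        ):
            logger.warning("trajectory contains points outside arena bounds (+/- %g cm)", tol)

    def __len__(self) -> int:
        return len(self.t)


_TRAJ_COLS = ["t", "nose_x", "nose_y", "center_x", "center_y", "tail_x", "tail_y"]


def read_trajectory(
    path: str | Path, arena_size: tuple[float, float] = (80.0, 80.0)
) -> TrackingTrajectory:
    """Read a videotracking CSV (columns ``t, nose_x … tail_y``).

    Rows with missing coordinates are masked, not dropped.  Fewer than 2
    samples is an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: trajectory needs at least 2 samples")
    return TrackingTrajectory(
        t=df["t"].to_numpy(dtype=float),
        nose=df[["nose_x", "nose_y"]].to_numpy(dtype=float),
        center=df[["center_x", "center_y"]].to_numpy(dtype=float),
        tail=df[["tail_x", "tail_y"]].to_numpy(dtype=float),
        arena_size=arena_size,
    )


def write_trajectory(traj: TrackingTrajectory, path: str | Path) -> None:
    pd.DataFrame({
        "t": traj.t,
        "nose_x": traj.nose[:, 0], "nose_y": traj.nose[:, 1],
        "center_x": traj.center[:, 0], "center_y": traj.center[:, 1],
        "tail_x": traj.tail[:, 0], "tail_y": traj.tail[:, 1],
    }).to_csv(path, index=False)


@dataclass
class ImageGrid:
    """Single- or multi-channel raster with a physical pixel size.

    ``pixel_size`` is the side length of a pixel in ``pixel_unit`` (default
    micrometres, the scale of fluorescence micrographs; landing photographs
    use centimetres).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    pixel_unit: str = "um"
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, which: int | str) -> "ImageGrid":
        if self.data.ndim != 3:
            raise ValueError("single-channel image has no channel axis")
        if isinstance(which, str):
            if self.channels is None or which not in self.channels:
                raise ValueError(f"unknown channel {which!r}")
            which = self.channels.index(which)
        return ImageGrid(self.data[..., which], self.pixel_size, self.pixel_unit)


_SUPPORTED_DTYPES = (np.uint8, np.uint16)


def read_image(
    path: str | Path,
    pixel_size: float = 1.0,
    pixel_unit: str = "um",
    channel: int | str | None = None,
) -> ImageGrid:
    """Read an 8/16-bit TIFF or PNG, preserving intensities bit-exactly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"{path}: unsupported bit depth {data.dtype}; need uint8 or uint16")
    channels = ("R", "G", "B")[: data.shape[-1]] if data.ndim == 3 else None
    grid = ImageGrid(data, pixel_size=pixel_size, pixel_unit=pixel_unit, channels=channels)
    if channel is not None:
        grid = grid.channel(channel)
    return grid


def write_image(grid: ImageGrid, path: str | Path) -> None:
    path = Path(path)
    data = grid.data
    if data.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"refusing to write dtype {data.dtype}; convert to uint8/uint16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


@dataclass
class AnimalRecord:
    """One animal × timepoint entry of a cohort, with payload references."""

    animal_id: str
    group: str
    timepoint: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


@dataclass
class PipelineConfig:
    """Tunable thresholds and conventions, serializable to/from YAML.

    Defaults are documented conventions (the acquisition protocols leave them
    open), not measured facts.
    """

    # stance / posturography
    min_paw_force: float = 5.0          # g: a paw is load-bearing above this
    min_stance_duration: float = 0.2    # s
    max_barycenter_speed: float = 2.0   # cm/s within a static epoch
    # open field
    smoothing_window: float = 0.5       # s boxcar before differentiation
    circling_min_speed: float = 18.0    # cm/s gate for "fast" laps (above normal gait)
    # imaging
    counting_frame_area: float = 425.10  # frame area as printed by the protocol
    colocalization_radius: float = 3.0   # um
    # misc
    arena_size: tuple[float, float] = (80.0, 80.0)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["arena_size"] = list(d["arena_size"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "arena_size" in d:
            d["arena_size"] = tuple(d["arena_size"])
        return cls(**d)
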