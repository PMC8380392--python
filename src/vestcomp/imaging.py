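"""Image-derived quantities.

* support surface — shoelace area of the quadrilateral delimited by the four
  paw pads on landing after tail suspension, averaged over repeated trials
  and expressed as a ratio to the preop session (preop ≡ 1);
* membrane fluorescence — background-thresholded (mean + 3·SD of a
  neuron-free region) per-cell mean intensity over the top band of each
  membrane ROI (pixels ≥ 80% of the ROI maximum after subtraction);
* counting-frame cell counts — connected-component blob detection inside a
  square counting frame, averaged over ~10 sections per animal;
* colocalization and survival percentages.

The cell detector is a synthetic-image stand-in for manual counting: it is
validated against planted blob positions, not against expert annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon
from skimage.measure import label, regionprops

from .core import ImageGrid

__all__ = [
    "PawQuad", "MembraneROISet", "CountingFrame",
    "support_surface", "support_surface_series",
    "membrane_intensity", "count_cells", "average_counts",
    "colocalization_pct", "survival_rate",
]


@dataclass(frozen=True)
class PawQuad:
    """Labeled paw-pad centroids of one landing photograph (cm)."""

    FL: tuple[float, float]
    FR: tuple[float, float]
    RL: tuple[float, float]
    RR: tuple[float, float]

    def perimeter_order(self) -> np.ndarray:
        """Vertices in perimeter order FL → FR → RR → RL."""
        return np.array([self.FL, self.FR, self.RR, self.RL], dtype=float)


def support_surface(quad: PawQuad) -> float:
    """Shoelace area (cm²) of the quadrilateral in perimeter order.

    Degenerate (collinear / duplicated) configurations return 0 with a
    warning rather than an error — they occur on real landing photos.
    """
    pts = quad.perimeter_order()
    if not np.all(np.isfinite(pts)):
        raise ValueError("paw coordinates must be finite")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0:
        warnings.warn("degenerate paw quadrilateral: zero support surface", stacklevel=2)
    return float(area)


def support_surface_series(
    sessions: dict[str, Sequence[PawQuad]], preop_key: str = "preop"
) -> dict[str, dict[str, float]]:
    """Per-session mean support surface, ratio-normalized to the preop session.

    Returns, per session, the trial count, the raw mean (cm²) and the
    normalized ratio (preop maps to exactly 1).  Raises if the preop mean is
    zero or the preop session is absent.
    """
    if preop_key not in sessions:
        raise ValueError(f"missing preop session {preop_key!r}")
    raw = {k: float(np.mean([support_surface(q) for q in v])) for k, v in sessions.items()}
    base = raw[preop_key]
    if base <= 0:
        raise ValueError("preop mean support surface is zero")
    return {
        k: {"n_trials": float(len(sessions[k])), "raw_cm2": raw[k], "ratio": raw[k] / base}
        for k in sessions
    }


def _region_mask(shape: tuple[int, int], region: np.ndarray) -> np.ndarray:
    """Boolean mask from a polygon (n≥3 vertices, row/col) or pixel list."""
    region = np.asarray(region)
    mask = np.zeros(shape, dtype=bool)
    if region.ndim != 2 or region.shape[1] != 2:
        raise ValueError("region must be (n, 2) vertices or pixel coordinates")
    if np.issubdtype(region.dtype, np.integer):
        mask[region[:, 0], region[:, 1]] = True
    else:
        rr, cc = draw_polygon(region[:, 0], region[:, 1], shape)
        mask[rr, cc] = True
    if not mask.any():
        raise ValueError("empty region")
    return mask


@dataclass
class MembraneROISet:
    """Background region (neuron-free) plus one membrane ROI per cell body.

    Regions are either float polygons (vertices, row/col) or integer pixel
    coordinate lists; background and membrane regions must not overlap.
    """

    background: np.ndarray
    membranes: list[np.ndarray] = field(default_factory=list)

    def masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, list[np.ndarray]]:
        bg = _region_mask(shape, self.background)
        mem = [_region_mask(shape, m) for m in self.membranes]
        for m in mem:
            if np.any(bg & m):
                raise ValueError("background and membrane regions overlap")
        return bg, mem


def membrane_intensity(
    image: ImageGrid, rois: MembraneROISet, top_band: float = 0.8,
    min_background_px: int = 50,
) -> dict:
    """Per-cell membrane fluorescence above a background-derived threshold.

    Threshold T = mean + 3·SD of the background region.  T is subtracted from
    the whole image and negative values discarded; within each membrane ROI
    the reported value is the mean of the retained pixels at or above
    ``top_band`` (default 80%) of the ROI maximum, restricting the average to
    the bright membrane band.  Cells with no pixel above T are flagged and
    excluded from the per-image mean.
    """
    data = np.asarray(image.data, dtype=float)
    if data.ndim != 2:
        raise ValueError("membrane_intensity expects a single-channel image")
    bg_mask, mem_masks = rois.masks(data.shape)
    if bg_mask.sum() < min_background_px:
        raise ValueError(f"background region below {min_background_px} pixels")
    bg = data[bg_mask]
    threshold = float(bg.mean() + 3.0 * bg.std(ddof=0))
    reduced = data - threshold

    per_cell: list[float] = []
    below: list[int] = []
    for i, m in enumerate(mem_masks):
        vals = reduced[m]
        vals = vals[vals > 0]
        if vals.size == 0:
            below.append(i)
            continue
        band = vals[vals >= top_band * vals.max()]
        per_cell.append(float(band.mean()))
    if below:
        warnings.warn(f"{len(below)} membrane ROI(s) entirely below threshold; excluded",
                      stacklevel=2)
    return {
        "threshold": threshold,
        "per_cell": per_cell,
        "below_threshold": below,
        "mean": float(np.mean(per_cell)) if per_cell else float("nan"),
    }


@dataclass(frozen=True)
class CountingFrame:
    """Square counting frame of given physical area, placed at an origin.

    ``area`` is in the squared unit of the image's ``pixel_size``; the frame
    side is √area.
    """

    area: float = 425.10
    origin: tuple[float, float] = (0.0, 0.0)   # top-left, physical units

    @property
    def side(self) -> float:
        return float(np.sqrt(self.area))

    def contains(self, rc: np.ndarray, pixel_size: float) -> np.ndarray:
        """Which (row, col) pixel centroids fall inside the frame."""
        phys = np.asarray(rc, dtype=float) * pixel_size
        r0, c0 = self.origin
        return (
            (phys[:, 0] >= r0) & (phys[:, 0] < r0 + self.side)
            & (phys[:, 1] >= c0) & (phys[:, 1] < c0 + self.side)
        )


def detect_blobs(
    image: ImageGrid, threshold: float | None = None, min_area_px: int = 4,
    background_sigmas: float = 3.0,
) -> np.ndarray:
    """Centroids (row, col, px) of bright blobs by threshold + connected components.

    With ``threshold=None`` the cutoff is the image median plus
    ``background_sigmas`` robust SDs (MAD-based) — adequate for sparse
    punctate staining on a dim background.
    """
    data = np.asarray(image.data, dtype=float)
    if threshold is None:
        med = np.median(data)
        mad = np.median(np.abs(data - med))
        threshold = med + background_sigmas * 1.4826 * (mad if mad > 0 else data.std() or 1.0)
    lab = label(data > threshold, connectivity=2)
    cents = [r.centroid for r in regionprops(lab) if r.area >= min_area_px]
    return np.array(cents, dtype=float).reshape(-1, 2)


def count_cells(
    image: ImageGrid, frame: CountingFrame, threshold: float | None = None,
    min_area_px: int = 4,
) -> int:
    """Number of detected cells whose centroid lies inside the counting frame."""
    cents = detect_blobs(image, threshold=threshold, min_area_px=min_area_px)
    if cents.size == 0:
        return 0
    return int(frame.contains(cents, image.pixel_size).sum())


def average_counts(section_counts: Sequence[float]) -> float:
    """Per-animal value: mean count across the ~10 assessed sections."""
    if len(section_counts) == 0:
        raise ValueError("no section counts")
    if not 8 <= len(section_counts) <= 12:
        warnings.warn(
            f"{len(section_counts)} sections outside the usual 10 ± 2 range", stacklevel=2
        )
    return float(np.mean(section_counts))


def colocalization_pct(
    marker_cells: np.ndarray, nuclear_cells: np.ndarray, match_radius: float = 3.0
) -> float:
    """Percent of marker-positive cells with a nuclear partner within radius.

    Greedy one-to-one matching by increasing distance.  Undefined (NaN) when
    there are no marker cells.
    """
    marker = np.asarray(marker_cells, dtype=float).reshape(-1, 2)
    nuclear = np.asarray(nuclear_cells, dtype=float).reshape(-1, 2)
    if marker.shape[0] == 0:
        warnings.warn("no marker-positive cells; colocalization undefined", stacklevel=2)
        return float("nan")
    if nuclear.shape[0] == 0:
        return 0.0
    tree = cKDTree(nuclear)
    pairs = tree.query_ball_point(marker, r=match_radius)
    candidates = sorted(
        (float(np.hypot(*(marker[i] - nuclear[j]))), i, j)
        for i, js in enumerate(pairs) for j in js
    )
    used_m: set[int] = set()
    used_n: set[int] = set()
    matched = 0
    for _, i, j in candidates:
        if i in used_m or j in used_n:
            continue
        used_m.add(i)
        used_n.add(j)
        matched += 1
    return 100.0 * matched / marker.shape[0]


def survival_rate(mean_count_d3: float, mean_count_d30: float) -> float:
    """Percent of the early proliferative cells persisting at the late timepoint."""
    if mean_count_d3 <= 0:
        raise ValueError("early (d3) mean count must be > 0")
    rate = 100.0 * mean_count_d30 / mean_count_d3
    if rate > 100.0:
        warnings.warn("survival rate above 100% (late count exceeds early count)",
                      stacklevel=2)
    return rate
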