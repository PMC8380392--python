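"""On-disk cohort layout: write a synthetic cohort as plain CSV + TIFF in the
exact formats the readers consume, and read it back.

Layout under the cohort root::

    cohort.yaml                     groups, timepoints, animal inventory
    dwb/<animal>_<tp>.csv           force-frame tables
    openfield/<animal>_<tp>.csv     trajectories
    tst/<animal>_<tp>.csv           paw-quad trials (trial, paw, x, y)
    checklists.csv                  one row per animal x timepoint
    cells/<animal>_<tp>/            per-section marker images + annotations
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .core import (
    AnimalRecord, read_force_frames, read_image, read_trajectory,
    write_force_frames, write_image, write_trajectory,
)
from .imaging import MembraneROISet, PawQuad
from .syndrome import SYMPTOM_WEIGHTS, SymptomChecklist
from .synthetic import Cohort, CohortConfig

__all__ = ["write_cohort", "read_cohort"]


def _quads_to_frame(quads: list[PawQuad]) -> pd.DataFrame:
    rows = []
    for i, q in enumerate(quads):
        for paw in ("FL", "FR", "RL", "RR"):
            x, y = getattr(q, paw)
            rows.append({"trial": i, "paw": paw, "x": x, "y": y})
    return pd.DataFrame(rows)


def _quads_from_frame(df: pd.DataFrame) -> list[PawQuad]:
    quads = []
    for _, trial in df.groupby("trial"):
        pos = {r["paw"]: (float(r["x"]), float(r["y"])) for _, r in trial.iterrows()}
        quads.append(PawQuad(**pos))
    return quads


def write_cohort(cohort: Cohort, root: str | Path) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    inventory = []
    checklist_rows = []
    for (aid, tp), rec in cohort.records.items():
        inventory.append({"animal_id": aid, "group": rec.group, "timepoint": tp,
                          "payloads": sorted(rec.payload)})
        if "force_frames" in rec.payload:
            (root / "dwb").mkdir(exist_ok=True)
            write_force_frames(rec.payload["force_frames"],
                               root / "dwb" / f"{aid}_{tp}.csv")
        if "trajectory" in rec.payload:
            (root / "openfield").mkdir(exist_ok=True)
            write_trajectory(rec.payload["trajectory"],
                             root / "openfield" / f"{aid}_{tp}.csv")
        if "paw_quads" in rec.payload:
            (root / "tst").mkdir(exist_ok=True)
            _quads_to_frame(rec.payload["paw_quads"]).to_csv(
                root / "tst" / f"{aid}_{tp}.csv", index=False)
        if "checklist" in rec.payload:
            row = {"animal_id": aid, "group": rec.group, "timepoint": tp}
            row.update({s: int(getattr(rec.payload["checklist"], s))
                        for s in SYMPTOM_WEIGHTS})
            checklist_rows.append(row)
        if "cells" in rec.payload:
            _write_cells(rec.payload["cells"], root / "cells" / f"{aid}_{tp}")
    if checklist_rows:
        pd.DataFrame(checklist_rows).to_csv(root / "checklists.csv", index=False)
    meta = {
        "groups": list(cohort.config.groups),
        "timepoints": list(cohort.config.timepoints),
        "seed": cohort.config.seed,
        "n_per_group": cohort.config.n_per_group,
    }
    (root / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def _write_cells(cells: dict, d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    for marker in ("iba1", "gfap", "brdu"):
        for i, sec in enumerate(cells[marker]):
            write_image(sec["image"], d / f"{marker}_s{i:02d}.tif")
            pd.DataFrame(sec["true_centroids"], columns=["row", "col"]).to_csv(
                d / f"{marker}_s{i:02d}_truth.csv", index=False)
            (d / f"{marker}_s{i:02d}_meta.yaml").write_text(
                yaml.safe_dump({"pixel_size": float(sec["image"].pixel_size)}))
    for i, sec in enumerate(cells["gr"]):
        write_image(sec["image"], d / f"gr_s{i:02d}.tif")
        pd.DataFrame(sec["nuclear_centroids"], columns=["row", "col"]).to_csv(
            d / f"gr_s{i:02d}_nuclear.csv", index=False)
        (d / f"gr_s{i:02d}_meta.yaml").write_text(
            yaml.safe_dump({"pixel_size": float(sec["image"].pixel_size)}))
    for i, sec in enumerate(cells["kcc2"]):
        write_image(sec["image"], d / f"kcc2_s{i:02d}.tif")
        rois: MembraneROISet = sec["rois"]
        rows = [{"roi": -1, "row": int(r), "col": int(c)} for r, c in rois.background]
        for j, mem in enumerate(rois.membranes):
            rows.extend({"roi": j, "row": int(r), "col": int(c)} for r, c in mem)
        pd.DataFrame(rows).to_csv(d / f"kcc2_s{i:02d}_rois.csv", index=False)


def _read_cells(d: Path) -> dict:
    out: dict = {}
    for marker in ("iba1", "gfap", "brdu"):
        sections = []
        for img_path in sorted(d.glob(f"{marker}_s??.tif")):
            meta = yaml.safe_load((d / f"{img_path.stem}_meta.yaml").read_text())
            img = read_image(img_path, pixel_size=meta["pixel_size"])
            truth = pd.read_csv(d / f"{img_path.stem}_truth.csv").to_numpy(dtype=float)
            sections.append({"image": img, "true_centroids": truth,
                             "n_true": len(truth)})
        out[marker] = sections
    gr_sections = []
    for img_path in sorted(d.glob("gr_s??.tif")):
        meta = yaml.safe_load((d / f"{img_path.stem}_meta.yaml").read_text())
        img = read_image(img_path, pixel_size=meta["pixel_size"])
        nuc = pd.read_csv(d / f"{img_path.stem}_nuclear.csv").to_numpy(dtype=float)
        gr_sections.append({"image": img, "nuclear_centroids": nuc})
    out["gr"] = gr_sections
    kcc2_sections = []
    for img_path in sorted(d.glob("kcc2_s??.tif")):
        img = read_image(img_path, pixel_size=1.0)
        roi_df = pd.read_csv(d / f"{img_path.stem}_rois.csv")
        bg = roi_df[roi_df["roi"] == -1][["row", "col"]].to_numpy(dtype=int)
        mems = [g[["row", "col"]].to_numpy(dtype=int)
                for roi, g in roi_df[roi_df["roi"] >= 0].groupby("roi")]
        kcc2_sections.append({"image": img,
                              "rois": MembraneROISet(background=bg, membranes=mems)})
    out["kcc2"] = kcc2_sections
    out["n_sections"] = len(out["iba1"])
    return out


def read_cohort(root: str | Path) -> Cohort:
    """Rebuild a :class:`Cohort` from its on-disk layout."""
    root = Path(root)
    meta = yaml.safe_load((root / "cohort.yaml").read_text())
    config = CohortConfig(n_per_group=meta.get("n_per_group", 1),
                          groups=tuple(meta["groups"]),
                          timepoints=tuple(meta["timepoints"]),
                          seed=meta.get("seed", 0))
    records: dict[tuple[str, str], AnimalRecord] = {}
    checklists: dict[tuple[str, str], SymptomChecklist] = {}
    group_of: dict[str, str] = {}
    cl_path = root / "checklists.csv"
    if cl_path.exists():
        df = pd.read_csv(cl_path)
        for _, r in df.iterrows():
            checklists[(r["animal_id"], r["timepoint"])] = SymptomChecklist(
                **{s: bool(r[s]) for s in SYMPTOM_WEIGHTS})
            group_of[r["animal_id"]] = r["group"]

    def _record(aid: str, tp: str) -> AnimalRecord:
        key = (aid, tp)
        if key not in records:
            group = group_of.get(aid) or next(
                g for g in meta["groups"] if aid.startswith(g))
            records[key] = AnimalRecord(aid, group, tp, {})
        return records[key]

    for sub, payload_key, reader in (
        ("dwb", "force_frames", read_force_frames),
        ("openfield", "trajectory", read_trajectory),
    ):
        for path in sorted((root / sub).glob("*.csv")) if (root / sub).exists() else []:
            aid, tp = path.stem.rsplit("_", 1)
            _record(aid, tp).payload[payload_key] = reader(path)
    if (root / "tst").exists():
        for path in sorted((root / "tst").glob("*.csv")):
            aid, tp = path.stem.rsplit("_", 1)
            _record(aid, tp).payload["paw_quads"] = _quads_from_frame(pd.read_csv(path))
    for (aid, tp), cl in checklists.items():
        _record(aid, tp).payload["checklist"] = cl
    if (root / "cells").exists():
        for d in sorted(p for p in (root / "cells").iterdir() if p.is_dir()):
            aid, tp = d.name.rsplit("_", 1)
            _record(aid, tp).payload["cells"] = _read_cells(d)
    return Cohort(config, records, pd.DataFrame())
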