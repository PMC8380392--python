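"""End-to-end orchestration: cohort → per-acquisition metrics → baseline
normalization → ANOVA/Tukey tables → plots and manifest.

Every metric is emitted as one tidy row (animal_id, group, timepoint, metric,
value, units, normalization) so all downstream statistics share one schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import PipelineConfig
from .imaging import (
    colocalization_pct, count_cells, CountingFrame, detect_blobs,
    membrane_intensity, support_surface_series, survival_rate,
)
from .kinematics import normalize_kinematics, path_metrics
from .posturography import (
    abdomen_load, barycenter_inertia, build_statokinesigram, circling_count,
    detect_stance_epochs, laterality_index, max_lateral_deviation,
    mean_lateral_position, rearing_fraction,
)
from .stats import groupwise_tukey
from .syndrome import syndrome_score
from .synthetic import Cohort

logger = logging.getLogger("vestcomp")

_TIDY_COLS = ["animal_id", "group", "timepoint", "metric", "value", "units",
              "normalization"]


def _row(aid: str, group: str, tp: str, metric: str, value: float,
         units: str, normalization: str) -> dict:
    return dict(zip(_TIDY_COLS, (aid, group, tp, metric, value, units, normalization)))


def dwb_metrics(cohort: Cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Posturographic metrics from the force streams of a cohort.

    Baseline-dependent metrics are NaN (with a logged warning upstream) for
    animals without a usable preop recording.
    """
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    for aid, group in cohort.animals():
        preop = cohort.records.get((aid, "preop"))
        preop_frames = preop.payload.get("force_frames") if preop else None
        preop_sk = None
        if preop_frames:
            ep = detect_stance_epochs(preop_frames, cfg.min_paw_force,
                                      cfg.min_stance_duration, cfg.max_barycenter_speed)
            if ep:
                preop_sk = build_statokinesigram(ep)
        for tp in cohort.config.timepoints:
            rec = cohort.records.get((aid, tp))
            if rec is None or "force_frames" not in rec.payload:
                continue
            frames = rec.payload["force_frames"]
            rows.append(_row(aid, group, tp, "laterality_index",
                             laterality_index(frames), "g", "raw"))
            rows.append(_row(aid, group, tp, "rearing_time",
                             rearing_fraction(frames, cfg.min_paw_force), "%", "raw"))
            if preop_frames:
                rows.append(_row(aid, group, tp, "abdomen_weight",
                                 abdomen_load(frames, preop_frames), "g",
                                 "preop-subtracted"))
            epochs = detect_stance_epochs(frames, cfg.min_paw_force,
                                          cfg.min_stance_duration,
                                          cfg.max_barycenter_speed)
            if epochs and preop_sk is not None:
                sk = build_statokinesigram(epochs)
                rows.append(_row(aid, group, tp, "mean_lateral_position",
                                 mean_lateral_position(sk, preop_sk), "cm",
                                 "preop-subtracted"))
                try:
                    rows.append(_row(aid, group, tp, "barycenter_inertia",
                                     barycenter_inertia(sk, preop_sk), "ratio",
                                     "preop-ratio"))
                    rows.append(_row(aid, group, tp, "max_lateral_deviation",
                                     max_lateral_deviation(sk, preop_sk), "ratio",
                                     "preop-ratio"))
                except ValueError:
                    logger.warning("degenerate preop statokinesigram for %s", aid)
    return pd.DataFrame(rows, columns=_TIDY_COLS)


def openfield_metrics(cohort: Cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Locomotor ratios, torsion differences and circling counts."""
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    for aid, group in cohort.animals():
        preop = cohort.records.get((aid, "preop"))
        preop_summary = None
        if preop is not None and "trajectory" in preop.payload:
            preop_summary = path_metrics(preop.payload["trajectory"],
                                         cfg.smoothing_window)
        for tp in cohort.config.timepoints:
            rec = cohort.records.get((aid, tp))
            if rec is None or "trajectory" not in rec.payload:
                continue
            traj = rec.payload["trajectory"]
            summary = path_metrics(traj, cfg.smoothing_window)
            rows.append(_row(aid, group, tp, "left_circling",
                             circling_count(traj, cfg.circling_min_speed, "left"),
                             "laps", "raw"))
            if preop_summary is None:
                continue
            norm = normalize_kinematics(summary, preop_summary)
            for metric, units in (("total_distance", "ratio"),
                                  ("mean_velocity", "ratio"),
                                  ("mean_acceleration", "ratio")):
                rows.append(_row(aid, group, tp, metric, norm[metric], units,
                                 "preop-ratio"))
            rows.append(_row(aid, group, tp, "mean_body_torsion",
                             norm["mean_body_torsion"], "deg", "preop-subtracted"))
    return pd.DataFrame(rows, columns=_TIDY_COLS)


def tst_metrics(cohort: Cohort) -> pd.DataFrame:
    """Support-surface session means, ratio-normalized to preop."""
    rows: list[dict] = []
    for aid, group in cohort.animals():
        sessions = {
            tp: rec.payload["paw_quads"]
            for tp in cohort.config.timepoints
            if (rec := cohort.records.get((aid, tp))) is not None
            and "paw_quads" in rec.payload
        }
        if "preop" not in sessions:
            logger.warning("no preop support-surface session for %s", aid)
            continue
        series = support_surface_series(sessions, preop_key="preop")
        for tp, vals in series.items():
            rows.append(_row(aid, group, tp, "support_surface", vals["ratio"],
                             "ratio", "preop-ratio"))
    return pd.DataFrame(rows, columns=_TIDY_COLS)


def checklist_scores(cohort: Cohort) -> pd.DataFrame:
    """Qualitative vestibular-syndrome scores."""
    rows: list[dict] = []
    for (aid, tp), rec in cohort.records.items():
        if "checklist" in rec.payload:
            rows.append(_row(aid, rec.group, tp, "syndrome_score",
                             float(syndrome_score(rec.payload["checklist"])),
                             "score", "raw"))
    return pd.DataFrame(rows, columns=_TIDY_COLS)


def cellular_metrics(cohort: Cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Marker quantification on the sacrificed subset.

    Blob counts per section are averaged per animal; GR nuclear localization
    is the colocalization percentage of detected GR cells with the nuclear
    centroids; the membrane marker reports the per-image mean of per-cell
    membrane fluorescence.
    """
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    for (aid, tp), rec in cohort.records.items():
        cells = rec.payload.get("cells")
        if not cells:
            continue
        group = rec.group
        for marker in ("iba1", "gfap", "brdu"):
            counts = []
            for sec in cells[marker]:
                img = sec["image"]
                side_px = np.sqrt(cfg.counting_frame_area) / img.pixel_size
                origin_px = (img.shape[0] - side_px) / 2
                frame = CountingFrame(area=cfg.counting_frame_area,
                                      origin=(origin_px * img.pixel_size,) * 2)
                counts.append(count_cells(img, frame))
            rows.append(_row(aid, group, tp, f"{marker}_count",
                             float(np.mean(counts)), "cells", "raw"))
        pcts = []
        for sec in cells["gr"]:
            detected = detect_blobs(sec["image"])
            radius_px = cfg.colocalization_radius / sec["image"].pixel_size
            pct = colocalization_pct(detected, sec["nuclear_centroids"],
                                     match_radius=radius_px)
            if np.isfinite(pct):
                pcts.append(pct)
        if pcts:
            rows.append(_row(aid, group, tp, "gr_dapi_pct",
                             float(np.mean(pcts)), "%", "raw"))
        intensities = []
        for sec in cells["kcc2"]:
            res = membrane_intensity(sec["image"], sec["rois"])
            if np.isfinite(res["mean"]):
                intensities.append(res["mean"])
        if intensities:
            rows.append(_row(aid, group, tp, "kcc2_intensity",
                             float(np.mean(intensities)), "a.u.", "raw"))
    return pd.DataFrame(rows, columns=_TIDY_COLS)


def survival_summary(cell_df: pd.DataFrame) -> pd.DataFrame:
    """Proliferative-cell survival (% of d3 counts persisting at d30).

    Computed per group on the group means of the proliferation-marker counts;
    a per-animal path is not available because different cohorts are
    sacrificed at each terminal day.
    """
    sub = cell_df[cell_df["metric"] == "brdu_count"]
    rows = []
    for group, g in sub.groupby("group"):
        d3 = g.loc[g["timepoint"] == "d3", "value"].mean()
        d30 = g.loc[g["timepoint"] == "d30", "value"].mean()
        if np.isfinite(d3) and d3 > 0 and np.isfinite(d30):
            rows.append({"group": group, "mean_d3": d3, "mean_d30": d30,
                         "survival_pct": survival_rate(d3, d30)})
    return pd.DataFrame(rows)


#: Behavioral metrics with complete within-animal series -> repeated design.
_REPEATED_METRICS = (
    "syndrome_score", "support_surface", "laterality_index", "rearing_time",
    "mean_body_torsion", "total_distance", "mean_velocity", "mean_acceleration",
    "left_circling", "abdomen_weight", "mean_lateral_position",
    "barycenter_inertia", "max_lateral_deviation",
)


def analyze_metrics(metrics: pd.DataFrame,
                    cellular: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA + Tukey for every metric; returns (anova table, comparisons table).

    Behavioral metrics use the split-plot (repeated) design over post-op
    time; cellular metrics use the independent two-way design (separate
    cohorts per terminal day).  Baseline-normalized metrics exclude preop
    (identically 0 or 1 by construction).
    """
    anova_rows = []
    comparison_tables = []

    def _one(df: pd.DataFrame, metric: str, repeated: bool) -> None:
        sub = df[df["metric"] == metric].rename(columns={"value": "value"})
        sub = sub.dropna(subset=["value"])
        norm = sub["normalization"].iloc[0] if len(sub) else "raw"
        if norm != "raw":
            sub = sub[sub["timepoint"] != "preop"]
        if sub["group"].nunique() < 2 or sub["timepoint"].nunique() < 2:
            return
        try:
            res, comps = groupwise_tukey(sub[["animal_id", "group", "timepoint",
                                              "value"]], repeated=repeated,
                                         analysis=metric)
        except ValueError as exc:
            logger.warning("skipping %s: %s", metric, exc)
            return
        for name in ("group", "time", "group x time"):
            e = res[name]
            anova_rows.append({"analysis": metric, "design": res.design,
                               "effect": name, "F": e.F, "df1": e.df,
                               "df2": res["error"].df if name != "group" or res.design == "independent"
                               else res["subjects"].df,
                               "p": e.p})
        comparison_tables.append(comps)

    for metric in metrics["metric"].unique():
        _one(metrics, metric, repeated=metric in _REPEATED_METRICS)
    if cellular is not None and len(cellular):
        for metric in cellular["metric"].unique():
            _one(cellular, metric, repeated=False)
    anova = pd.DataFrame(anova_rows)
    comps = (pd.concat(comparison_tables, ignore_index=True)
             if comparison_tables else pd.DataFrame())
    return anova, comps


def run_pipeline(
    cohort: Cohort,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    stages: Sequence[str] = ("dwb", "openfield", "tst", "checklist", "cells"),
    make_plots: bool = True,
) -> dict:
    """Quantify a cohort end to end and write all output tables.

    Writes ``metrics.csv`` (tidy per-acquisition metrics), ``cellular.csv``,
    ``anova.csv``, ``comparisons.csv`` (summary-table format),
    ``survival.csv``, optional plots, and ``manifest.json``.  Stages whose
    payloads are absent are skipped and recorded in the manifest.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    parts: list[pd.DataFrame] = []
    cellular = pd.DataFrame()
    stage_fns = {"dwb": lambda: dwb_metrics(cohort, cfg),
                 "openfield": lambda: openfield_metrics(cohort, cfg),
                 "tst": lambda: tst_metrics(cohort),
                 "checklist": lambda: checklist_scores(cohort)}
    for stage in stages:
        try:
            if stage == "cells":
                cellular = cellular_metrics(cohort, cfg)
                status[stage] = "ok" if len(cellular) else "no data"
            else:
                df = stage_fns[stage]()
                if len(df):
                    parts.append(df)
                    status[stage] = "ok"
                else:
                    status[stage] = "no data"
        except Exception as exc:  # per-stage error records, keep going
            logger.error("stage %s failed: %s", stage, exc)
            status[stage] = f"error: {exc}"
    metrics = (pd.concat(parts, ignore_index=True)
               if parts else pd.DataFrame(columns=_TIDY_COLS))
    metrics.to_csv(outdir / "metrics.csv", index=False)
    if len(cellular):
        cellular.to_csv(outdir / "cellular.csv", index=False)
        survival_summary(cellular).to_csv(outdir / "survival.csv", index=False)
    anova, comps = analyze_metrics(metrics, cellular if len(cellular) else None)
    anova.to_csv(outdir / "anova.csv", index=False)
    comps.to_csv(outdir / "comparisons.csv", index=False)
    if make_plots:
        try:
            from .plots import plot_statokinesigram_grid, plot_timecourses
            plot_timecourses(metrics, outdir / "timecourses.png")
            plot_statokinesigram_grid(cohort, cfg, outdir / "statokinesigrams.png")
            status["plots"] = "ok"
        except Exception as exc:
            logger.error("plotting failed: %s", exc)
            status["plots"] = f"error: {exc}"
    manifest = {
        "version": __version__,
        "seed": cohort.config.seed,
        "n_per_group": cohort.config.n_per_group,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": status,
        "n_metric_rows": int(len(metrics)),
        "n_comparisons": int(len(comps)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"metrics": metrics, "cellular": cellular, "anova": anova,
            "comparisons": comps, "manifest": manifest}
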