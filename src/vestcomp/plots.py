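"""Diagnostic plots: statokinesigrams and metric time courses."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import PAWS, PipelineConfig, TIMEPOINT_DAYS
from .posturography import build_statokinesigram, detect_stance_epochs
from .synthetic import Cohort

_PAW_COLORS = {"FL": "#e78ac3", "FR": "#66c2a5", "RL": "#fc8d62", "RR": "#8da0cb"}


def plot_statokinesigram(sk, ax=None, title: str = "") -> None:
    """Barycenter trace and paw clouds; antero-posterior axis on the abscissa."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for p in PAWS:
        cloud = sk.paw_clouds[p]
        ax.scatter(cloud[:, 0], cloud[:, 1], s=6, alpha=0.5,
                   color=_PAW_COLORS[p], label=p)
        ax.plot(*cloud.mean(axis=0), "k+", markersize=10)
    xy = sk.xy
    ax.scatter(xy[:, 0], xy[:, 1], s=8, color="green", alpha=0.7, label="barycenter")
    mx, my = sk.weighted_mean
    ax.plot(mx, my, "ro", markersize=7)
    ax.set_xlabel("antero-posterior (cm)")
    ax.set_ylabel("lateral (cm)")
    ax.set_title(title, fontsize=9)
    ax.set_aspect("equal")


def plot_statokinesigram_grid(cohort: Cohort, cfg: PipelineConfig,
                              path: str | Path, timepoint: str = "d3") -> None:
    """One representative statokinesigram per group at one timepoint."""
    groups = cohort.config.groups
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 4))
    axes = np.atleast_1d(axes)
    for ax, group in zip(axes, groups):
        rec = next((r for (aid, tp), r in cohort.records.items()
                    if r.group == group and tp == timepoint
                    and "force_frames" in r.payload), None)
        if rec is None:
            ax.set_axis_off()
            continue
        epochs = detect_stance_epochs(rec.payload["force_frames"],
                                      cfg.min_paw_force, cfg.min_stance_duration,
                                      cfg.max_barycenter_speed)
        if not epochs:
            ax.set_axis_off()
            continue
        plot_statokinesigram(build_statokinesigram(epochs), ax=ax,
                             title=f"{group} {timepoint}")
    axes[0].legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_timecourses(metrics: pd.DataFrame, path: str | Path) -> None:
    """Group-mean ± SEM time course per metric."""
    metric_names = list(metrics["metric"].unique())
    if not metric_names:
        return
    ncol = 3
    nrow = int(np.ceil(len(metric_names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, metric in zip(axes.flat, metric_names):
        sub = metrics[metrics["metric"] == metric].dropna(subset=["value"])
        for group, g in sub.groupby("group"):
            agg = g.groupby("timepoint")["value"].agg(["mean", "sem", "count"])
            agg["day"] = [TIMEPOINT_DAYS[tp] for tp in agg.index]
            agg = agg.sort_values("day")
            ax.errorbar(agg["day"], agg["mean"], yerr=agg["sem"], label=group,
                        marker="o", markersize=3, capsize=2)
        ax.set_title(metric, fontsize=9)
        ax.set_xlabel("post-operative day")
    for ax in axes.flat[len(metric_names):]:
        ax.set_axis_off()
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
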