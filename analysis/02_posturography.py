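#!/usr/bin/env python
"""Dynamic-weight-bearing quantification of the simulated cohort.

Reads results/cohort/, computes laterality index, rearing time, abdomen
load, and the barycenter metrics (mean lateral position, inertia ratio,
maximum lateral deviation), and writes the tidy table plus representative
statokinesigrams.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.cohort_io import read_cohort
from vestcomp.core import PipelineConfig
from vestcomp.pipeline import dwb_metrics
from vestcomp.plots import plot_statokinesigram_grid


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    cfg = PipelineConfig()
    metrics = dwb_metrics(cohort, cfg)
    metrics.to_csv(RESULTS / "metrics_posturography.csv", index=False)
    plot_statokinesigram_grid(cohort, cfg, RESULTS / "statokinesigrams_d3.png",
                              timepoint="d3")
    print(f"{len(metrics)} metric rows -> {RESULTS / 'metrics_posturography.csv'}")
    d3 = metrics[metrics.timepoint == "d3"]
    for m in ("laterality_index", "rearing_time", "abdomen_weight"):
        print(f"\n{m} at d3 (group means):")
        print(d3[d3.metric == m].groupby("group")["value"].mean().round(2).to_string())


if __name__ == "__main__":
    main()
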