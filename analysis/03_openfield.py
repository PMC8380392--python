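#!/usr/bin/env python
"""Open-field quantification: locomotion ratios, body torsion, circling."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.cohort_io import read_cohort
from vestcomp.pipeline import openfield_metrics


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    metrics = openfield_metrics(cohort)
    metrics.to_csv(RESULTS / "metrics_openfield.csv", index=False)
    print(f"{len(metrics)} metric rows -> {RESULTS / 'metrics_openfield.csv'}")
    for m, tps in (("mean_body_torsion", ("d1", "d3")),
                   ("left_circling", ("d3",)),
                   ("mean_velocity", ("d1", "d30"))):
        sub = metrics[metrics.metric == m]
        for tp in tps:
            print(f"\n{m} at {tp} (group means):")
            print(sub[sub.timepoint == tp].groupby("group")["value"]
                  .mean().round(2).to_string())


if __name__ == "__main__":
    main()
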