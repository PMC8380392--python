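#!/usr/bin/env python
"""Image-based quantification: landing support surface after tail
suspension, marker cell counts in the counting frame, GR nuclear
localization, membrane fluorescence, and the proliferative-cell survival
percentage."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.cohort_io import read_cohort
from vestcomp.pipeline import cellular_metrics, survival_summary, tst_metrics


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    support = tst_metrics(cohort)
    cells = cellular_metrics(cohort)
    support.to_csv(RESULTS / "metrics_support_surface.csv", index=False)
    cells.to_csv(RESULTS / "metrics_cellular.csv", index=False)
    print(f"{len(support)} support rows, {len(cells)} cellular rows")

    print("\nsupport-surface ratio at d7 (group means):")
    d7 = support[support.timepoint == "d7"]
    print(d7.groupby("group")["value"].mean().round(3).to_string())

    print("\ncell counts (group x day means):")
    for m in ("iba1_count", "gfap_count", "brdu_count", "gr_dapi_pct",
              "kcc2_intensity"):
        sub = cells[cells.metric == m]
        if len(sub):
            tab = sub.pivot_table(index="group", columns="timepoint",
                                  values="value").round(2)
            print(f"\n{m}:")
            print(tab.to_string())

    surv = survival_summary(cells)
    surv.to_csv(RESULTS / "survival.csv", index=False)
    print("\nproliferative-cell survival (% of d3 persisting at d30):")
    print(surv.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
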