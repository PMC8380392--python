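#!/usr/bin/env python
"""Qualitative vestibular-syndrome scores (tumbling 5, retropulsion 4,
circling 3, bobbing 2, head tilt 1) over post-operative time."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.cohort_io import read_cohort
from vestcomp.core import TIMEPOINT_DAYS
from vestcomp.pipeline import checklist_scores


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort")
    scores = checklist_scores(cohort)
    scores.to_csv(RESULTS / "metrics_syndrome.csv", index=False)
    tab = scores.pivot_table(index="group", columns="timepoint", values="value")
    tab = tab[sorted(tab.columns, key=TIMEPOINT_DAYS.get)]
    print("mean syndrome score (0-15) per group and timepoint:")
    print(tab.round(2).to_string())


if __name__ == "__main__":
    main()
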