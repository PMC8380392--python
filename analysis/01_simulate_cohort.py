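#!/usr/bin/env python
"""Generate the synthetic study cohort and write it to disk.

Three groups (sham, UVN + placebo, UVN + met) followed from the
pre-operative baseline to post-operative day 30.  Acquisitions are
shortened (60 s) and the cohort reduced to 6 animals/group so the on-disk
dataset stays small; the statistical structure (kinetics, noise, effect
sizes) is the package default.  Output: results/cohort/ in the exact
layouts the readers consume, plus the latent intensity table.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.cohort_io import write_cohort
from vestcomp.synthetic import CohortConfig, simulate_cohort


def main(seed: int = 1) -> None:
    cfg = CohortConfig(n_per_group=6, seed=seed, cells_per_group_per_day=2,
                       sections_mean=8).scaled_down()
    cohort = simulate_cohort(cfg)
    out = RESULTS / "cohort"
    write_cohort(cohort, out)
    cohort.latent.to_csv(RESULTS / "latent_intensity.csv", index=False)
    n_img = sum(1 for _ in out.rglob("*.tif"))
    print(f"cohort: {len(cohort.records)} records "
          f"({cfg.n_per_group}/group x {len(cfg.timepoints)} timepoints), "
          f"{n_img} micrographs -> {out}")
    by_group = cohort.latent[cohort.latent.day == 3].groupby("group")["s"].mean()
    print("latent syndrome intensity at d3 (group means):")
    print(by_group.round(3).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
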