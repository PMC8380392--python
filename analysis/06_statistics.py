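#!/usr/bin/env python
"""Statistical layer over all quantified metrics.

Behavioral metrics: split-plot (1-between "group", 1-within "time") ANOVA;
cellular metrics: independent two-way ANOVA (separate cohorts per terminal
day).  Both are followed by per-delay Tukey contrasts between groups,
emitted in the summary-table format (means, SE of diff, q, DF, p, stars).
Also re-derives the published worked q examples from their printed means.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from vestcomp.pipeline import analyze_metrics
from vestcomp.stats import tukey_from_means

WORKED = [
    ("IBA1 d3", 46.8, 8.33, 5.86, 67),
    ("GFAP d3", 49.6, 16.1, 4.5, 63),
    ("abdomen d30", -1.76, 7.31, 2.46, 34),
    ("inertia d30", 1.29, 3.81, 0.868, 38),
    ("left circling d3", 1.38, 7.4, 1.37, 51),
]


def main() -> None:
    parts = []
    for name in ("metrics_posturography", "metrics_openfield",
                 "metrics_support_surface", "metrics_syndrome"):
        path = RESULTS / f"{name}.csv"
        if path.exists():
            parts.append(pd.read_csv(path))
    metrics = pd.concat(parts, ignore_index=True)
    cellular_path = RESULTS / "metrics_cellular.csv"
    cellular = pd.read_csv(cellular_path) if cellular_path.exists() else None

    anova, comps = analyze_metrics(metrics, cellular)
    anova.to_csv(RESULTS / "anova.csv", index=False)
    comps.to_csv(RESULTS / "comparisons.csv", index=False)
    print(f"{len(anova)} ANOVA effects, {len(comps)} Tukey contrasts")

    sig = comps[(comps.p < 0.05)
                & (comps.group_1.isin(["UVN_met", "UVN_placebo"]))
                & (comps.group_2.isin(["UVN_met", "UVN_placebo"]))]
    print(f"\nsignificant placebo-vs-met contrasts ({len(sig)}):")
    cols = ["analysis", "delay", "mean_1", "mean_2", "se_diff", "q", "df", "p"]
    print(sig[cols].round(3).to_string(index=False))

    print("\nworked examples from printed group means (q recomputed):")
    for label, m1, m2, se, df in WORKED:
        row = tukey_from_means(m1, m2, se, df, k=3)
        print(f"  {label:18s} q = {row.q:6.3f}  p = {row.p:.4f} {row.stars}")


if __name__ == "__main__":
    main()
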