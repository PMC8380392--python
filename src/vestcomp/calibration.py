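"""Monte-Carlo calibration utilities and simulation oracles.

These functions exercise the real analysis chain on simulated data:

* family-wise type-I error of the two-way-ANOVA → Tukey chain under a
  complete null;
* rejection rate of the D'Agostino–Pearson normality screen on normal data;
* an independent Monte-Carlo estimate of the studentized-range upper tail
  (direct simulation of ranges of normal samples over an independent χ
  scale), used to cross-check the numerically integrated tail probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import normality_screen, tukey_critical_q, tukey_pairs, two_way_anova

__all__ = [
    "tukey_chain_type_i_error", "dagostino_rejection_rate",
    "studentized_range_mc_sf",
]


def tukey_chain_type_i_error(
    n_replicates: int = 2000,
    n_per_cell: int = 8,
    n_groups: int = 3,
    n_times: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of the ANOVA→Tukey chain under the null.

    Each replicate draws i.i.d. standard-normal data for a ``n_groups`` ×
    ``n_times`` independent design, runs the two-way ANOVA, and performs
    Tukey contrasts over the single family of all group × time cell means
    against the residual error term; a replicate counts as a rejection when
    any contrast is significant at ``alpha`` (its q exceeds the
    studentized-range critical value — the same decision as p < alpha).
    Tukey's procedure is exact under this complete null, so the rate
    should sit at ~alpha.
    """
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per_cell * n_times)
    tps = np.tile(np.repeat([f"t{j}" for j in range(n_times)], n_per_cell), n_groups)
    aids = [f"a{i}" for i in range(len(groups))]
    base = pd.DataFrame({"animal_id": aids, "group": groups, "timepoint": tps})
    k_family = n_groups * n_times
    q_crit: float | None = None
    rejections = 0
    for _ in range(n_replicates):
        df = base.copy()
        df["value"] = rng.normal(size=len(df))
        res = two_way_anova(df, repeated=False)
        ms, dferr = res.error_terms["residual"]
        if q_crit is None:
            q_crit = tukey_critical_q(alpha, k_family, dferr)
        cells = df.groupby(["group", "timepoint"])["value"]
        means = {f"{g}|{t}": m for (g, t), m in cells.mean().items()}
        sizes = {f"{g}|{t}": n for (g, t), n in cells.count().items()}
        rows = tukey_pairs(means, sizes, ms, dferr, k=k_family, compute_p=False)
        if max(r.q for r in rows) > q_crit:
            rejections += 1
    return rejections / n_replicates


def dagostino_rejection_rate(
    n_replicates: int = 1000, n: int = 200, alpha: float = 0.05, seed: int = 0,
    distribution: str = "normal",
) -> float:
    """Rejection rate of the normality screen on simulated samples.

    ``distribution="normal"`` estimates the size (should be ~alpha);
    ``"lognormal"`` estimates power against a strongly skewed alternative.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        if distribution == "normal":
            x = rng.normal(size=n)
        elif distribution == "lognormal":
            x = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        if normality_screen(x).p < alpha:
            rejections += 1
    return rejections / n_replicates


def studentized_range_mc_sf(
    q: float, k: int, df: int, n_draws: int = 1_000_000, seed: int = 0,
    batch: int = 200_000,
) -> float:
    """Monte-Carlo estimate of P(Q > q) for the studentized range.

    Simulates ranges of ``k`` independent standard normals divided by an
    independent χ/√df scale — a direct construction that shares no code with
    the numerically integrated tail.
    """
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_draws:
        m = min(batch, n_draws - done)
        z = rng.normal(size=(m, k))
        rng_range = z.max(axis=1) - z.min(axis=1)
        s = np.sqrt(rng.chisquare(df, size=m) / df)
        exceed += int((rng_range / s > q).sum())
        done += m
    return exceed / n_draws
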