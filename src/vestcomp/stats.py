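"""Statistical layer: normality screening, two-way ANOVA (independent and
1-between/1-within split-plot), and Tukey multiple comparisons.

Tukey rows are reported in the study's summary-table format: the two cell
means, the standard error of their difference, the studentized-range ratio

    q = sqrt(2) * |mean_1 - mean_2| / se_diff,

the error degrees of freedom, and the Tukey-adjusted p from the studentized
range distribution with ``k`` means in the family (default: the number of
groups compared at a given delay) — the convention recovered by recomputing
the published worked examples.

The split-plot ANOVA tests the group factor against the subject-within-group
mean square and the time and interaction factors against the within-subject
residual; no sphericity correction is applied by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "NormalityResult", "AnovaEffect", "AnovaResult", "ComparisonRow",
    "normality_screen", "two_way_anova", "tukey_pairs", "tukey_from_means",
    "studentized_range_p", "p_stars", "comparisons_to_frame",
]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float          # D'Agostino–Pearson omnibus K²
    p: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def normality_screen(values: np.ndarray) -> NormalityResult:
    """D'Agostino–Pearson omnibus normality test plus Q–Q plot coordinates.

    Requires n ≥ 8 (the omnibus statistic combines skewness and kurtosis
    z-scores, both undefined below that); constant samples are an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError(f"normality screen needs n >= 8, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = scipy.stats.normaltest(x)
    (theo, ordered), _ = scipy.stats.probplot(x, dist="norm")
    return NormalityResult(float(stat), float(p), theo, ordered)


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    design: str                       # "independent" | "repeated"
    effects: dict[str, AnovaEffect]
    #: error strata available for post hoc tests: name -> (MS, df)
    error_terms: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


_REQUIRED_COLS = ("animal_id", "group", "timepoint", "value")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    df = table.dropna(subset=["value"]).copy()
    if df["group"].nunique() < 2 or df["timepoint"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 timepoints")
    return df


def _independent_anova(df: pd.DataFrame) -> AnovaResult:
    model = smf.ols("value ~ C(group) * C(timepoint)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    res_ms = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    res_df = int(tab.loc["Residual", "df"])
    effects = {}
    for row, name in (("C(group)", "group"), ("C(timepoint)", "time"),
                      ("C(group):C(timepoint)", "group x time")):
        ss = float(tab.loc[row, "sum_sq"])
        dfe = int(tab.loc[row, "df"])
        effects[name] = AnovaEffect(name, ss, dfe, ss / dfe,
                                    float(tab.loc[row, "F"]), float(tab.loc[row, "PR(>F)"]))
    effects["error"] = AnovaEffect("error", res_ms * res_df, res_df, res_ms,
                                   float("nan"), float("nan"))
    return AnovaResult("independent", effects, {"residual": (res_ms, res_df)})


def _split_plot_anova(df: pd.DataFrame) -> AnovaResult:
    pivot = df.pivot_table(index=["group", "animal_id"], columns="timepoint",
                           values="value", aggfunc="mean")
    complete = pivot.dropna()
    dropped = len(pivot) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} animal(s) with incomplete time series",
                      stacklevel=3)
    if complete.index.get_level_values("group").nunique() < 2 or complete.shape[1] < 2:
        raise ValueError("fewer than 2 complete groups or timepoints after dropping")
    Y = complete.to_numpy(dtype=float)
    glabels = complete.index.get_level_values("group").to_numpy()
    groups = pd.unique(glabels)
    N, T = Y.shape
    G = len(groups)
    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    m_t = Y.mean(axis=0)
    ss_group = ss_subj = ss_int = ss_err = 0.0
    for g in groups:
        sel = glabels == g
        Yg = Y[sel]
        m_g = Yg.mean()
        m_gt = Yg.mean(axis=0)
        n_g = sel.sum()
        ss_group += T * n_g * (m_g - grand) ** 2
        ss_subj += T * ((subj_mean[sel] - m_g) ** 2).sum()
        ss_int += n_g * ((m_gt - m_g - m_t + grand) ** 2).sum()
        ss_err += ((Yg - subj_mean[sel][:, None] - m_gt[None, :] + m_g) ** 2).sum()
    ss_time = N * ((m_t - grand) ** 2).sum()
    df_group, df_subj = G - 1, N - G
    df_time, df_int, df_err = T - 1, (G - 1) * (T - 1), (N - G) * (T - 1)
    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err

    def eff(name: str, ss: float, dfe: int, ms_denom: float, df_denom: int) -> AnovaEffect:
        ms = ss / dfe
        F = ms / ms_denom
        return AnovaEffect(name, ss, dfe, ms, F, float(scipy.stats.f.sf(F, dfe, df_denom)))

    effects = {
        "group": eff("group", ss_group, df_group, ms_subj, df_subj),
        "time": eff("time", ss_time, df_time, ms_err, df_err),
        "group x time": eff("group x time", ss_int, df_int, ms_err, df_err),
        "subjects": AnovaEffect("subjects", ss_subj, df_subj, ms_subj, float("nan"), float("nan")),
        "error": AnovaEffect("error", ss_err, df_err, ms_err, float("nan"), float("nan")),
    }
    return AnovaResult("repeated", effects,
                       {"within": (ms_err, df_err), "subjects": (ms_subj, df_subj)})


def two_way_anova(table: pd.DataFrame, repeated: bool = False) -> AnovaResult:
    """Two-factor ANOVA of a (animal_id, group, timepoint, value) table.

    ``repeated=False``: ordinary two-factor ANOVA with interaction (type-II
    sums of squares).  ``repeated=True``: split-plot design with group
    between subjects and timepoint within; animals with incomplete series
    are dropped with a warning.
    """
    df = _validate_table(table)
    return _split_plot_anova(df) if repeated else _independent_anova(df)


def studentized_range_p(q: float, k: int, df: float) -> float:
    """Upper-tail probability of the studentized range (numerical integration)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    if q == 0:
        return 1.0
    return float(scipy.stats.studentized_range.sf(q, k, df))


def p_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonRow:
    """One Tukey contrast in the summary-table format."""

    analysis: str
    delay: str
    label_1: str
    label_2: str
    mean_1: float
    mean_2: float
    se_diff: float
    q: float
    df: float
    p: float

    @property
    def stars(self) -> str:
        return p_stars(self.p)


def tukey_from_means(
    mean_1: float, mean_2: float, se_diff: float, df: float, k: int = 3,
    analysis: str = "", delay: str = "", label_1: str = "", label_2: str = "",
) -> ComparisonRow:
    """Tukey contrast from already-computed cell means and SE of difference.

    This is the entry point for re-deriving published table rows: q =
    √2·|Δmean|/se_diff and the adjusted p from the studentized range with
    ``k`` means (default 3 groups) and ``df`` error degrees of freedom.
    """
    if se_diff <= 0:
        raise ValueError("se_diff must be > 0")
    q = float(np.sqrt(2.0) * abs(mean_1 - mean_2) / se_diff)
    return ComparisonRow(analysis, delay, label_1, label_2,
                         mean_1, mean_2, se_diff, q, df, studentized_range_p(q, k, df))


def tukey_pairs(
    means: dict[str, float],
    sizes: dict[str, int],
    error_ms: float,
    error_df: float,
    k: int | None = None,
    pairs: list[tuple[str, str]] | None = None,
    analysis: str = "",
    delay: str = "",
    compute_p: bool = True,
) -> list[ComparisonRow]:
    """All pairwise Tukey contrasts among ``means``.

    ``se_diff`` uses the Tukey–Kramer form √(MSE·(1/n₁ + 1/n₂)), which
    reduces to √(2·MSE/n) for equal cell sizes.  ``k`` defaults to the number
    of means in the family.  ``compute_p=False`` skips the (comparatively
    slow) studentized-range tail evaluation, leaving p = NaN — useful in
    simulation loops that threshold q against a pre-inverted critical value.
    """
    if error_df <= 0:
        raise ValueError("error df must be > 0")
    if error_ms <= 0:
        raise ValueError("error mean square must be > 0")
    if k is None:
        k = len(means)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(means), 2))
    rows = []
    for a, b in pairs:
        se = float(np.sqrt(error_ms * (1.0 / sizes[a] + 1.0 / sizes[b])))
        if compute_p:
            rows.append(tukey_from_means(means[a], means[b], se, error_df, k=k,
                                         analysis=analysis, delay=delay,
                                         label_1=a, label_2=b))
        else:
            q = float(np.sqrt(2.0) * abs(means[a] - means[b]) / se)
            rows.append(ComparisonRow(analysis, delay, a, b, means[a], means[b],
                                      se, q, error_df, float("nan")))
    return rows


def tukey_critical_q(alpha: float, k: int, df: float) -> float:
    """Critical studentized-range value: q with upper-tail probability alpha."""
    from scipy.optimize import brentq

    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(brentq(lambda q: studentized_range_p(q, k, df) - alpha, 1e-6, 100.0))


def comparisons_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Tidy comparisons table mirroring the published summary-table columns."""
    return pd.DataFrame([
        {"analysis": r.analysis, "delay": r.delay,
         "group_1": r.label_1, "group_2": r.label_2,
         "mean_1": r.mean_1, "mean_2": r.mean_2, "se_diff": r.se_diff,
         "q": r.q, "df": r.df, "p": r.p, "stars": r.stars}
        for r in rows
    ])


def groupwise_tukey(
    table: pd.DataFrame, repeated: bool = False, analysis: str = "",
) -> tuple[AnovaResult, pd.DataFrame]:
    """ANOVA followed by per-delay Tukey contrasts between groups.

    The error term is the within-subject residual for the repeated design and
    the ANOVA residual otherwise; the family size is the number of groups.
    """
    df = _validate_table(table)
    res = two_way_anova(df, repeated=repeated)
    ms, dferr = res.error_terms["within" if repeated else "residual"]
    k = df["group"].nunique()
    rows: list[ComparisonRow] = []
    for tp, sub in df.groupby("timepoint", sort=False):
        means = sub.groupby("group")["value"].mean().to_dict()
        sizes = sub.groupby("group")["value"].count().to_dict()
        rows.extend(tukey_pairs(means, sizes, ms, dferr, k=k,
                                analysis=analysis, delay=str(tp)))
    return res, comparisons_to_frame(rows)
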