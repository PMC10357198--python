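"""Replicate-hierarchy statistics and the study summary table.

The study's unit of analysis is the animal (biological replicate): technical
replicate values are averaged per animal first, then group statistics
(mean +/- SD) and hypothesis tests are computed over animal means only.
Tests: two-sample Student's t (pooled variance; Welch behind a flag),
one-factor ANOVA with Tukey-Kramer pairwise adjustment (studentized-range
quantiles, unequal-n standard errors), and two-factor ANOVA with Type II sums
of squares.  Significance stars: *** p<0.001, ** p<0.01, * p<0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "stars",
    "aggregate",
    "t_test",
    "anova_tukey",
    "two_factor_anova",
    "build_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary over biological replicates (animal means)."""

    group_id: str
    measure_id: str
    animal_means: pd.Series  # indexed by animal_id
    group_mean: float
    group_sd: float  # over animal means, ddof=1 (nan when n_bio == 1)
    n_bio: int


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    df: float
    p: float
    stars: str
    method: str = ""
    flags: tuple = ()


def stars(p: float) -> str:
    """Map a p-value to the study's significance labels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate(measurements: pd.DataFrame, measure_id: str = "",
              group_id: str | None = None) -> GroupSummary:
    """Two-level aggregation: technical -> animal means -> group mean/SD.

    ``measurements`` needs columns [group_id, animal_id, value] (tech_rep
    optional); all rows must belong to one group unless ``group_id`` selects
    it.  The SD is computed over animal means only (n_bio - 1 denominator).
    """
    df = measurements
    if group_id is not None:
        df = df[df["group_id"] == group_id]
    if len(df) == 0:
        raise ValueError("empty group: nothing to aggregate")
    groups = df["group_id"].unique()
    if len(groups) != 1:
        raise ValueError(f"expected one group, got {sorted(groups)}")
    animal_means = df.groupby("animal_id")["value"].mean()
    n_bio = len(animal_means)
    return GroupSummary(
        group_id=str(groups[0]),
        measure_id=measure_id,
        animal_means=animal_means,
        group_mean=float(animal_means.mean()),
        group_sd=float(animal_means.std(ddof=1)) if n_bio > 1 else float("nan"),
        n_bio=n_bio,
    )


def t_test(a: GroupSummary, b: GroupSummary, welch: bool = False) -> TestResult:
    """Two-sample two-tailed t-test on animal means.

    Student's pooled-variance test by default (the study's named test);
    ``welch=True`` switches to the unequal-variance form.  Degenerate inputs
    (zero pooled variance) give p=1 for equal means and p=0, flagged
    ``degenerate``, for unequal means.
    """
    xa = a.animal_means.to_numpy(dtype=float)
    xb = b.animal_means.to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("both groups need n_bio >= 2 for a t-test")
    label = f"{a.group_id} vs {b.group_id}"
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        if xa[0] == xb[0]:
            return TestResult(label, 0.0, len(xa) + len(xb) - 2, 1.0, "ns",
                              method="student_t")
        return TestResult(label, np.inf, len(xa) + len(xb) - 2, 0.0, "***",
                          method="student_t", flags=("degenerate",))
    res = sps.ttest_ind(xa, xb, equal_var=not welch)
    df = float(res.df)
    return TestResult(label, float(res.statistic), df, float(res.pvalue),
                      stars(float(res.pvalue)),
                      method="welch_t" if welch else "student_t")


def anova_tukey(summaries: list[GroupSummary]) -> list[TestResult]:
    """One-factor ANOVA plus Tukey-Kramer pairwise comparisons.

    Returns the omnibus F-test result followed by one result per group pair,
    with studentized-range adjusted p-values (Kramer's unequal-n standard
    errors).  With fewer than 3 groups, use :func:`t_test` instead.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 groups for ANOVA + Tukey; use t_test")
    samples = [s.animal_means.to_numpy(dtype=float) for s in summaries]
    if any(len(x) < 2 for x in samples):
        raise ValueError("every group needs n_bio >= 2")
    F = sps.f_oneway(*samples)
    k = len(samples)
    df_err = sum(len(x) for x in samples) - k
    results = [TestResult(
        "omnibus", float(F.statistic), float(df_err), float(F.pvalue),
        stars(float(F.pvalue)), method="anova_1f",
    )]
    tk = sps.tukey_hsd(*samples)
    for i in range(k):
        for j in range(i + 1, k):
            p = float(tk.pvalue[i, j])
            diff = float(np.mean(samples[i]) - np.mean(samples[j]))
            results.append(TestResult(
                f"{summaries[i].group_id} vs {summaries[j].group_id}",
                diff, float(df_err), p, stars(p), method="tukey_kramer",
            ))
    return results


def two_factor_anova(df: pd.DataFrame, value: str = "value",
                     factor_a: str = "group_id",
                     factor_b: str = "level") -> list[TestResult]:
    """Two-factor ANOVA (Type II SS) with interaction.

    Returns main effects for both factors and the interaction.  When factor B
    has a single level the design degenerates to the one-factor ANOVA.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df[[value, factor_a, factor_b]].dropna().copy()
    if len(d) == 0:
        raise ValueError("no complete observations")
    counts = d.groupby([factor_a, factor_b], observed=True).size()
    n_cells = d[factor_a].nunique() * d[factor_b].nunique()
    if len(counts) < n_cells or counts.min() == 0:
        raise ValueError("design has an all-missing cell")
    d = d.rename(columns={value: "y", factor_a: "A", factor_b: "B"})
    if d["B"].nunique() < 2:
        groups = [g["y"].to_numpy() for _, g in d.groupby("A")]
        F = sps.f_oneway(*groups)
        dfe = len(d) - len(groups)
        return [TestResult(f"{factor_a} (one-factor)", float(F.statistic),
                           float(dfe), float(F.pvalue),
                           stars(float(F.pvalue)), method="anova_1f")]
    model = smf.ols("y ~ C(A) * C(B)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = []
    labels = {"C(A)": factor_a, "C(B)": factor_b,
              "C(A):C(B)": f"{factor_a}:{factor_b}"}
    for row, label in labels.items():
        if row not in tab.index:
            continue
        p = float(tab.loc[row, "PR(>F)"])
        out.append(TestResult(label, float(tab.loc[row, "F"]),
                              float(tab.loc[row, "df"]), p, stars(p),
                              method="anova_2f_typeII"))
    return out


# measure_id -> (table row label, unit scale applied for display)
REPORT_ROWS = [
    ("g_loss_low", "G'' [Pa], at low-gamma shear oscillation"),
    ("E_high", "E [kPa], at high-eps compression"),
    ("elastin_ratio", "Released alpha-elastin from tissue [ug/mg]"),
    ("histo_cross", "Elastin in tissue section [%]: cross"),
    ("histo_mid", "Elastin in tissue section [%]: mid-tangential"),
]


def build_report(
    summaries: dict[str, dict[str, GroupSummary]],
    fit_block: dict | None = None,
    groups: tuple[str, str] = ("Fb-P", "Fb-PECM"),
) -> tuple[pd.DataFrame, dict]:
    """Assemble the study summary table (mean +/- SD per group, p, stars).

    ``summaries`` maps measure_id -> {group_id -> GroupSummary}.  Emits one
    row per available headline measure; missing measures are skipped with a
    warning.  Returns (table, metrics) where metrics is a flat JSON-ready
    dict also carrying the model-fit block when given.
    """
    rows = []
    metrics: dict = {}
    for measure_id, label in REPORT_ROWS:
        if measure_id not in summaries:
            warnings.warn(f"measure {measure_id!r} missing; row omitted",
                          stacklevel=2)
            continue
        per_group = summaries[measure_id]
        if not all(g in per_group for g in groups):
            warnings.warn(f"measure {measure_id!r} lacks groups {groups}; "
                          "row omitted", stacklevel=2)
            continue
        a, b = (per_group[g] for g in groups)
        test = t_test(a, b)
        rows.append({
            "measure": label,
            groups[0]: f"{a.group_mean:.3g} ± {a.group_sd:.2g}",
            groups[1]: f"{b.group_mean:.3g} ± {b.group_sd:.2g}",
            "p": test.p,
            "stars": test.stars,
        })
        for s in (a, b):
            metrics[f"{measure_id}.{s.group_id}"] = s.group_mean
        metrics[f"{measure_id}.p"] = test.p
    if fit_block:
        for key, val in fit_block.items():
            metrics[f"fit.{key}"] = val
    table = pd.DataFrame(rows)
    if len(rows) == 0:
        warnings.warn("no measures available: empty report", stacklevel=2)
    return table, metrics
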