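"""Group comparisons used throughout the study's quantitative analysis.

Covers the pooled two-sample t-test (from raw samples or from printed
mean / SEM / n summaries — the two agree exactly by construction),
the Mann-Whitney U test (exact enumeration at small n, tie-corrected normal
approximation otherwise), one-way ANCOVA (a two-level factor plus one
continuous covariate, reported in both sequential orders and Type II), and
the two-way repeated-measures (mixed) ANOVA with a Bonferroni paired-t
post-hoc helper.  A Shapiro-Wilk gate routes two-sample comparisons to the
t-test or Mann-Whitney depending on normality, mirroring the study's
statistical workflow.

Pooled (not Welch) variance is the default for the t-test: it reproduces
every printed degrees-of-freedom pair; Welch is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "pooled_t_summary",
    "pooled_t_raw",
    "mann_whitney",
    "ancova_one_way",
    "rm_anova_two_way",
    "bonferroni_paired_t",
    "shapiro_gate",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: mean, SEM and sample size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sem <= 0:
            raise ValueError("sem must be > 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass
class TestResult:
    """Statistic, degrees of freedom, two-sided p and a method tag."""

    statistic: float
    df: float | tuple
    p_value: float
    method: str


def pooled_t_summary(a: GroupSummary, b: GroupSummary, welch: bool = False) -> TestResult:
    """Two-sample t-test from summary statistics.

    SD_i = SEM_i * sqrt(n_i); pooled variance with df = n1 + n2 - 2 (or
    Welch-Satterthwaite when ``welch``); two-sided p.
    """
    v1, v2 = a.sd**2, b.sd**2
    if welch:
        se2 = v1 / a.n + v2 / b.n
        t = (a.mean - b.mean) / math.sqrt(se2)
        df = se2**2 / ((v1 / a.n) ** 2 / (a.n - 1) + (v2 / b.n) ** 2 / (b.n - 1))
        method = "welch_t"
    else:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * v1 + (b.n - 1) * v2) / df
        t = (a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        method = "pooled_t"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p_value=float(p), method=method)


def pooled_t_raw(x, y, welch: bool = False) -> TestResult:
    """Two-sample t-test from raw data; equals the summary route exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    a = GroupSummary(float(np.mean(x)), float(np.std(x, ddof=1) / math.sqrt(len(x))), len(x))
    b = GroupSummary(float(np.mean(y)), float(np.std(y, ddof=1) / math.sqrt(len(y))), len(y))
    return pooled_t_summary(a, b, welch=welch)


def mann_whitney(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the U null distribution when n1 + n2 <= 12 and the
    data are tie-free; tie-corrected normal approximation (with continuity
    correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        df=float("nan"),
        p_value=float(res.pvalue),
        method=f"mann_whitney_{method}",
    )


def ancova_one_way(value, factor, covariate) -> dict:
    """One-way ANCOVA: value ~ factor (2 levels) + covariate.

    Returns sequential (Type I) F tests in both term orders plus Type II,
    each as a ``TestResult`` keyed ``"<order>_<term>"``; the primary pair is
    ``factor_first_factor`` / ``factor_first_covariate``.  A constant
    covariate skips the covariate tests (flagged under ``"covariate_skipped"``).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"value": value, "factor": factor, "covariate": covariate})
    levels = df["factor"].unique()
    if len(levels) != 2:
        raise ValueError("factor must have exactly 2 levels")
    if df.groupby("factor").size().min() < 3:
        raise ValueError("need at least 3 observations per factor level")
    out: dict[str, TestResult | bool] = {"covariate_skipped": False}
    cov_constant = np.ptp(df["covariate"].to_numpy()) == 0

    def seq(formula: str, order_tag: str, terms: list[str]):
        fit = smf.ols(formula, data=df).fit()
        tab = anova_lm(fit, typ=1)
        for term, tag in terms:
            row = tab.loc[term]
            out[f"{order_tag}_{tag}"] = TestResult(
                statistic=float(row["F"]),
                df=(float(row["df"]), float(tab.loc["Residual", "df"])),
                p_value=float(row["PR(>F)"]),
                method=f"ancova_typeI_{order_tag}",
            )
        return fit

    if cov_constant:
        out["covariate_skipped"] = True
        fit = smf.ols("value ~ C(factor)", data=df).fit()
        tab = anova_lm(fit, typ=1)
        row = tab.loc["C(factor)"]
        res = TestResult(
            statistic=float(row["F"]),
            df=(float(row["df"]), float(tab.loc["Residual", "df"])),
            p_value=float(row["PR(>F)"]),
            method="anova_factor_only",
        )
        out["factor_first_factor"] = res
        out["typeII_factor"] = res
        return out

    fit = seq(
        "value ~ C(factor) + covariate", "factor_first",
        [("C(factor)", "factor"), ("covariate", "covariate")],
    )
    seq(
        "value ~ covariate + C(factor)", "covariate_first",
        [("covariate", "covariate"), ("C(factor)", "factor")],
    )
    tab2 = anova_lm(fit, typ=2)
    for term, tag in [("C(factor)", "factor"), ("covariate", "covariate")]:
        row = tab2.loc[term]
        out[f"typeII_{tag}"] = TestResult(
            statistic=float(row["F"]),
            df=(float(row["df"]), float(tab2.loc["Residual", "df"])),
            p_value=float(row["PR(>F)"]),
            method="ancova_typeII",
        )
    out["model"] = fit
    return out


def rm_anova_two_way(
    table: pd.DataFrame,
    subject: str = "cell",
    between: str = "genotype",
    within: str = "condition",
    dv: str = "value",
) -> dict[str, TestResult]:
    """Mixed two-way ANOVA: between-subject group, within-subject condition.

    The design must be balanced within subjects (every subject measured in
    every condition); unbalanced input raises an error naming the offending
    subjects.  Returns TestResults keyed ``group``, ``condition``,
    ``interaction`` — with 6 + 4 subjects and 3 conditions the df pattern is
    group (1, 8), condition and interaction (2, 16).
    """
    import pingouin as pg

    conditions = sorted(table[within].unique())
    bad = [
        str(s)
        for s, sub in table.groupby(subject)
        if sorted(sub[within]) != conditions
    ]
    if bad:
        raise ValueError(f"unbalanced within-subject data for subjects: {', '.join(bad)}")
    if table.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    n_group = table[between].nunique()
    n_cond = len(conditions)
    n_subj = table[subject].nunique()
    if np.ptp(table[dv].to_numpy()) == 0:
        # degenerate all-equal input: every effect is exactly zero
        df_between = (float(n_group - 1), float(n_subj - n_group))
        df_within = (float(n_cond - 1), float((n_subj - n_group) * (n_cond - 1)))
        return {
            "group": TestResult(0.0, df_between, 1.0, "mixed_anova"),
            "condition": TestResult(0.0, df_within, 1.0, "mixed_anova"),
            "interaction": TestResult(0.0, df_within, 1.0, "mixed_anova"),
        }
    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, between=between, subject=subject
    ).set_index("Source")
    key_map = {between: "group", within: "condition", "Interaction": "interaction"}
    out = {}
    for source, key in key_map.items():
        row = aov.loc[source]
        out[key] = TestResult(
            statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p_value=float(row["p_unc"]),
            method="mixed_anova",
        )
    return out


def bonferroni_paired_t(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    group: str | None = None,
    subject: str = "cell",
    within: str = "condition",
    dv: str = "value",
    between: str = "genotype",
) -> list[dict]:
    """Paired t-tests between conditions with Bonferroni correction.

    ``group`` restricts to one between-subject level.  The corrected p is
    min(1, p * number_of_pairs).
    """
    sub = table if group is None else table[table[between] == group]
    wide = sub.pivot(index=subject, columns=within, values=dv)
    m = len(pairs)
    results = []
    for a, b in pairs:
        t, p = sps.ttest_rel(wide[a], wide[b])
        results.append(
            {
                "pair": (a, b),
                "t": float(t),
                "df": len(wide) - 1,
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return results


def shapiro_gate(x, y, alpha: float = 0.05) -> TestResult:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk is applied to each group; if both look normal (p > alpha)
    the pooled t-test is used, otherwise Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    normal = sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    res = pooled_t_raw(x, y) if normal else mann_whitney(x, y)
    res.method = f"shapiro_gate:{res.method}"
    return res
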