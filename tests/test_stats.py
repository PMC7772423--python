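"""Group statistics: printed-value reproduction and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ionclamp import stats as st
from ionclamp.stats import GroupSummary


# ---------------------------------------------------------------------------
# pooled t
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,t_expected",
    [
        # inverse slope factors, maximal conductances, half-activation voltages
        ((17.77, 2.36, 15), (11.92, 1.06, 14), 2.206),
        ((67.89, 17.59, 15), (39.81, 5.58, 14), 1.478),
        ((-23.87, 7.07, 15), (-35.79, 3.96, 14), 1.441),
    ],
)
def test_pooled_t_reproduces_reported_group_comparisons(a, b, t_expected):
    res = st.pooled_t_summary(GroupSummary(*a), GroupSummary(*b))
    assert res.df == 27
    assert res.statistic == pytest.approx(t_expected, rel=0.01)


def test_pooled_t_equal_means_and_antisymmetry(rng):
    a = GroupSummary(5.0, 1.0, 10)
    assert st.pooled_t_summary(a, a).statistic == 0.0
    assert st.pooled_t_summary(a, a).p_value == 1.0
    x, y = rng.normal(size=12), rng.normal(1.0, 1.0, 9)
    assert st.pooled_t_raw(x, y).statistic == pytest.approx(
        -st.pooled_t_raw(y, x).statistic
    )


def test_raw_and_summary_routes_agree_exactly(rng):
    for _ in range(100):
        x = rng.normal(0, 2, rng.integers(3, 20))
        y = rng.normal(1, 1, rng.integers(3, 20))
        raw = st.pooled_t_raw(x, y)
        summ = st.pooled_t_summary(
            GroupSummary(x.mean(), x.std(ddof=1) / np.sqrt(len(x)), len(x)),
            GroupSummary(y.mean(), y.std(ddof=1) / np.sqrt(len(y)), len(y)),
        )
        assert abs(raw.statistic - summ.statistic) < 1e-12
        assert abs(raw.p_value - summ.p_value) < 1e-12


def test_textbook_pooled_t_value():
    res = st.pooled_t_raw([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert res.df == 4
    assert res.statistic == pytest.approx(-1.2247, abs=1e-4)


def test_welch_flag_changes_df_under_unequal_variance():
    a = GroupSummary(0.0, 0.2, 10)
    b = GroupSummary(1.0, 2.0, 10)
    assert st.pooled_t_summary(a, b, welch=True).df < st.pooled_t_summary(a, b).df


def test_identical_arrays_give_zero_t():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert st.pooled_t_raw(x, x).statistic == 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_complete_separation_exact():
    res = st.mann_whitney([1.0, 2.0], [3.0, 4.0])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0 / 3.0)
    assert res.method == "mann_whitney_exact"


def test_mann_whitney_tied_singletons():
    res = st.mann_whitney([5.0], [5.0])
    assert res.statistic == 0.5  # n1*n2/2 under full ties


def _mwu_permutation_p(x, y):
    """Full-enumeration two-sided p over all group labellings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mid = len(x) * len(y) / 2
    stat_obs = abs(u_obs - mid)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        count += abs(u - mid) >= stat_obs - 1e-12
        total += 1
    return count / total


def test_mann_whitney_matches_full_enumeration(rng):
    for _ in range(25):
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1.0, 5)
        res = st.mann_whitney(x, y)
        assert res.p_value == pytest.approx(_mwu_permutation_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


def _ancova_data(rng, n=15, effect=0.0, cov_effect=0.0):
    factor = np.repeat(["a", "b"], n)
    cov = rng.normal(10, 3, 2 * n)
    value = (
        effect * (factor == "b") + cov_effect * cov + rng.normal(0, 1, 2 * n)
    )
    return value, factor, cov


def test_ancova_coefficients_match_normal_equations(rng):
    for _ in range(25):
        value, factor, cov = _ancova_data(rng, effect=rng.normal(), cov_effect=rng.normal())
        out = st.ancova_one_way(value, factor, cov)
        x = np.column_stack([np.ones(len(value)), (factor == "b").astype(float), cov])
        beta = np.linalg.lstsq(x, value, rcond=None)[0]
        np.testing.assert_allclose(out["model"].params.to_numpy(), beta, atol=1e-10)


def test_ancova_sequential_ss_oracle(rng):
    """Type I F values equal the explicit RSS-difference construction."""
    value, factor, cov = _ancova_data(rng, effect=1.0, cov_effect=0.5)
    out = st.ancova_one_way(value, factor, cov)

    def rss(*columns):
        x = np.column_stack([np.ones(len(value)), *columns])
        beta = np.linalg.lstsq(x, value, rcond=None)[0]
        return float(np.sum((value - x @ beta) ** 2))

    dummy = (factor == "b").astype(float)
    rss_full = rss(dummy, cov)
    df_resid = len(value) - 3
    f_factor = (rss() - rss(dummy)) / (rss_full / df_resid)
    f_cov = (rss(dummy) - rss_full) / (rss_full / df_resid)
    assert out["factor_first_factor"].statistic == pytest.approx(f_factor, abs=1e-10)
    assert out["factor_first_covariate"].statistic == pytest.approx(f_cov, abs=1e-10)


def test_ancova_detects_factor_not_null_covariate(rng):
    """Large factor effect, null covariate: factor F big, covariate F ~ 1."""
    f_factor, f_cov = [], []
    for _ in range(60):
        value, factor, cov = _ancova_data(rng, n=15, effect=3.0, cov_effect=0.0)
        out = st.ancova_one_way(value, factor, cov)
        f_factor.append(out["factor_first_factor"].p_value)
        f_cov.append(out["factor_first_covariate"].statistic)
    assert np.median(f_factor) < 1e-6
    assert 0.3 < np.mean(f_cov) < 3.0  # E[F] ~ df2/(df2-2) ~ 1 under the null


def test_ancova_constant_covariate_skipped(rng):
    value, factor, _ = _ancova_data(rng)
    out = st.ancova_one_way(value, factor, np.full(len(value), 7.0))
    assert out["covariate_skipped"] is True
    assert "factor_first_covariate" not in out


def test_ancova_contract_errors(rng):
    value, factor, cov = _ancova_data(rng, n=2)
    with pytest.raises(ValueError, match="3 observations"):
        st.ancova_one_way(value, factor, cov)
    with pytest.raises(ValueError, match="2 levels"):
        st.ancova_one_way([1.0, 2.0, 3.0], ["a", "b", "c"], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# mixed (two-way repeated-measures) ANOVA
# ---------------------------------------------------------------------------


def _long_table(values, groups=("g1", "g2"), n_per_group=(6, 4), conditions=("c1", "c2", "c3")):
    rows = []
    it = iter(values)
    for g, n in zip(groups, n_per_group):
        for s in range(n):
            for c in conditions:
                rows.append(
                    {"cell": f"{g}_{s}", "genotype": g, "condition": c, "value": next(it)}
                )
    return pd.DataFrame(rows)


def _mixed_anova_oracle(df):
    """Cell-means sums-of-squares decomposition for balanced designs."""
    k = df["condition"].nunique()
    groups = df["genotype"].unique()
    grand = df["value"].mean()
    m_g = df.groupby("genotype")["value"].mean()
    m_c = df.groupby("condition")["value"].mean()
    m_gc = df.groupby(["genotype", "condition"])["value"].mean()
    m_s = df.groupby("cell")["value"].mean()
    subj_group = df.groupby("cell")["genotype"].first()
    n_subj = len(m_s)
    n_g = subj_group.value_counts()

    ss_group = k * sum(n_g[g] * (m_g[g] - grand) ** 2 for g in groups)
    ss_cond = n_subj * sum((m_c[c] - grand) ** 2 for c in m_c.index)
    ss_inter = sum(
        n_g[g] * (m_gc[(g, c)] - m_g[g] - m_c[c] + grand) ** 2
        for g in groups for c in m_c.index
    )
    ss_subj = k * sum((m_s[s] - m_g[subj_group[s]]) ** 2 for s in m_s.index)
    ss_err = sum(
        (row.value - m_gc[(row.genotype, row.condition)]
         - m_s[row.cell] + m_g[row.genotype]) ** 2
        for row in df.itertuples()
    )
    df_group, df_subj = len(groups) - 1, n_subj - len(groups)
    df_cond = k - 1
    df_err = df_subj * df_cond
    return {
        "group": ss_group / df_group / (ss_subj / df_subj),
        "condition": ss_cond / df_cond / (ss_err / df_err),
        "interaction": ss_inter / (df_group * df_cond) / (ss_err / df_err),
    }


def test_mixed_anova_df_pattern_six_plus_four():
    rng = np.random.default_rng(1)
    df = _long_table(rng.normal(size=30))
    res = st.rm_anova_two_way(df)
    assert res["group"].df == (1.0, 8.0)
    assert res["condition"].df == (2.0, 16.0)
    assert res["interaction"].df == (2.0, 16.0)


def test_mixed_anova_matches_ss_oracle(rng):
    for _ in range(10):
        df = _long_table(rng.normal(size=30), n_per_group=(5, 5))
        res = st.rm_anova_two_way(df)
        oracle = _mixed_anova_oracle(df)
        for key in ("group", "condition", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], abs=1e-10)


def test_mixed_anova_all_equal_is_null():
    df = _long_table(np.ones(30))
    res = st.rm_anova_two_way(df)
    assert all(res[k].statistic == 0.0 for k in res)


def test_mixed_anova_unbalanced_raises_with_subject_names():
    rng = np.random.default_rng(2)
    df = _long_table(rng.normal(size=30))
    df = df[~((df["cell"] == "g1_0") & (df["condition"] == "c3"))]
    with pytest.raises(ValueError, match="g1_0"):
        st.rm_anova_two_way(df)


def test_bonferroni_paired_t_helper(rng):
    df = _long_table(rng.normal(size=30))
    pairs = [("c1", "c2"), ("c2", "c3"), ("c1", "c3")]
    res = st.bonferroni_paired_t(df, pairs, group="g1")
    assert len(res) == 3
    wide = df[df["genotype"] == "g1"].pivot(index="cell", columns="condition", values="value")
    t_ref, p_ref = sps.ttest_rel(wide["c1"], wide["c2"])
    assert res[0]["t"] == pytest.approx(t_ref)
    assert res[0]["p_bonferroni"] == pytest.approx(min(1.0, p_ref * 3))


# ---------------------------------------------------------------------------
# Shapiro-Wilk gate
# ---------------------------------------------------------------------------


def test_shapiro_gate_routes_by_distribution():
    routes = {"normal": [], "heavy": []}
    for seed in range(20):
        rng = np.random.default_rng(seed)
        routes["normal"].append(
            st.shapiro_gate(rng.normal(size=25), rng.normal(0.5, 1, 25)).method
        )
        routes["heavy"].append(
            st.shapiro_gate(rng.standard_cauchy(25), rng.standard_cauchy(25)).method
        )
    t_rate = np.mean(["pooled_t" in m for m in routes["normal"]])
    mwu_rate = np.mean(["mann_whitney" in m for m in routes["heavy"]])
    assert t_rate >= 0.8
    assert mwu_rate >= 0.8
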