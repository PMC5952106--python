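"""Rubin's-rules pooling: hand-checked examples and complete-data reductions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from miprofile import (
    BehavioralTable,
    pooled_anova,
    pooled_correlation,
    pooled_profile_means,
    pooled_t_test,
    rubin_pool,
)
from miprofile.imputation import ImputationSet
from miprofile.pooling import PoolingError

from conftest import make_small_table


def test_rubin_pool_zero_between_variance():
    p = rubin_pool([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
    assert (p.point, p.within_var, p.between_var, p.total_var) == (2.0, 1.0, 0.0, 1.0)


def test_rubin_pool_hand_computed_example():
    p = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    assert p.point == pytest.approx(2.0)
    assert p.within_var == pytest.approx(1.0)
    assert p.between_var == pytest.approx(1.0)
    assert p.total_var == pytest.approx(7.0 / 3.0)
    # large-sample df: (m-1) (1 + W/((1+1/m)B))^2 = 2 * (1 + 3/4)^2 = 6.125
    assert p.df == pytest.approx(2 * (1 + 0.75) ** 2)


def test_rubin_pool_variance_linearity():
    base = rubin_pool([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    doubled = rubin_pool([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
    assert doubled.within_var == pytest.approx(2 * base.within_var)
    assert doubled.total_var - (4 / 3) * doubled.between_var == pytest.approx(
        2 * (base.total_var - (4 / 3) * base.between_var)
    )


def test_rubin_pool_m1_warns_and_uses_complete_df():
    with pytest.warns(UserWarning):
        p = rubin_pool([5.0], [2.0], df_complete=17.0)
    assert (p.point, p.total_var, p.df) == (5.0, 2.0, 17.0)


def test_rubin_pool_barnard_rubin_df_below_large_sample_df():
    large = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    adj = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], df_complete=20.0)
    assert 0 < adj.df < large.df
    assert adj.df != int(adj.df)  # fractional, as pooled dfs typically are


def test_rubin_pool_rejects_bad_input():
    with pytest.raises(PoolingError):
        rubin_pool([1.0, 2.0], [1.0, -1.0])


def _labeled_set(dfs, labels):
    tables = [BehavioralTable(df) for df in dfs]
    return ImputationSet(method="pmm", tables=tables), labels


def _two_group_table(seed=0, na=30, nb=25, shift=0.0):
    rng = np.random.default_rng(seed)
    table = make_small_table(n=na + nb, seed=seed)
    table.df["ran"] = np.concatenate(
        [rng.normal(100 + shift, 12, na), rng.normal(100, 10, nb)]
    )
    labels = np.array(["Control"] * na + ["PoorDecoder"] * nb)
    return table, labels


def test_single_imputation_t_equals_welch():
    table, labels = _two_group_table(seed=1, shift=6.0)
    tset = ImputationSet(method="mean_replacement", tables=[table])
    t, df, p, d = pooled_t_test(tset, labels, "Control", "PoorDecoder", "ran")
    a = table.df.loc[labels == "Control", "ran"]
    b = table.df.loc[labels == "PoorDecoder", "ran"]
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)
    assert df == pytest.approx(ref.df)


def test_identical_groups_give_zero_t_and_d():
    rng = np.random.default_rng(2)
    table = make_small_table(n=50, seed=2)
    vals = rng.normal(100, 12, 25)
    table.df["ran"] = np.concatenate([vals, vals])  # both groups identical
    labels = np.array(["Control"] * 25 + ["PoorDecoder"] * 25)
    tset = ImputationSet(method="pmm", tables=[table] * 3)
    t, df_, p, d = pooled_t_test(tset, labels, "Control", "PoorDecoder", "ran")
    assert abs(t) < 1e-9
    assert abs(d) < 1e-9


def test_cohens_d_recovers_generating_effect():
    """Two well-separated groups: pooled d tracks (mu_a - mu_b)/sigma."""
    ds = []
    for k in range(30):
        rng = np.random.default_rng(100 + k)
        n = 80
        table = make_small_table(n=2 * n, seed=k)
        table.df["ran"] = np.concatenate(
            [rng.normal(130, 10, n), rng.normal(100, 10, n)]
        )
        labels = np.array(["Control"] * n + ["PoorDecoder"] * n)
        tset = ImputationSet(method="mean_replacement", tables=[table])
        ds.append(pooled_t_test(tset, labels, "Control", "PoorDecoder", "ran")[3])
    se = np.std(ds, ddof=1) / np.sqrt(len(ds))
    assert abs(np.mean(ds) - 3.0) < 3 * se + 0.05


def test_single_imputation_correlation_equals_pearson():
    table, labels = _two_group_table(seed=3)
    rng = np.random.default_rng(3)
    table.df["verbal_iq"] = table.df["ran"] * 0.5 + rng.normal(0, 5, table.n)
    tset = ImputationSet(method="mean_replacement", tables=[table])
    r, df, p = pooled_correlation(tset, labels, "Control", "ran", "verbal_iq")
    sub = table.df.loc[labels == "Control"]
    ref_r, ref_p = stats.pearsonr(sub["ran"], sub["verbal_iq"])
    assert r == pytest.approx(ref_r)
    assert df == pytest.approx(len(sub) - 2)
    assert p == pytest.approx(ref_p, rel=1e-6)


def test_exact_copy_gives_r_one():
    table, labels = _two_group_table(seed=4)
    table.df["verbal_iq"] = table.df["ran"]
    tset = ImputationSet(method="mean_replacement", tables=[table])
    r, df, p = pooled_correlation(tset, labels, "Control", "ran", "verbal_iq")
    assert r == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_pooled_r_bounded_by_one(seed):
    """Fisher-z pooling keeps |r| <= 1 for arbitrary imputation spread."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(3):
        t = make_small_table(n=20, seed=seed % 100)
        t.df["ran"] = rng.normal(100, 10, 20)
        t.df["verbal_iq"] = 0.9 * t.df["ran"] + rng.normal(0, 2, 20)
        tables.append(t)
    labels = np.array(["Control"] * 20)
    tset = ImputationSet(method="pmm", tables=tables)
    r, df, p = pooled_correlation(tset, labels, "Control", "ran", "verbal_iq")
    assert -1.0 <= r <= 1.0


def test_anova_f_equals_t_squared_for_two_groups():
    table, labels = _two_group_table(seed=5, shift=8.0)
    tset = ImputationSet(method="mean_replacement", tables=[table])
    res = pooled_anova(tset, labels, "ran")
    a = table.df.loc[labels == "Control", "ran"]
    b = table.df.loc[labels == "PoorDecoder", "ran"]
    t_pooled = stats.ttest_ind(a, b, equal_var=True)
    assert res["F"] == pytest.approx(t_pooled.statistic**2, rel=1e-9)
    assert res["p"] == pytest.approx(t_pooled.pvalue, rel=1e-6)


def test_anova_zero_between_variance_gives_zero_eta2():
    table, labels = _two_group_table(seed=6)
    df2 = table.df.copy()
    vals = np.tile(np.arange(5, dtype=float), 11)
    df2["ran"] = vals
    df2 = df2.iloc[:55]
    labels2 = np.array((["Control"] * 5 + ["PoorDecoder"] * 5) * 5 + ["Control"] * 5)
    tset = ImputationSet(method="mean_replacement", tables=[BehavioralTable(df2)])
    res = pooled_anova(tset, labels2, "ran")
    assert res["eta_squared"] < 0.01


def test_anova_recovers_validation_orderings(training_cohort):
    """The validation-score generator's built-in orderings come back out
    of the pooled ANOVA: Controls beat every reading-disability profile."""
    from miprofile import ValidationModel, generate_validation_scores

    table = generate_validation_scores(training_cohort, ValidationModel(seed=77))
    labels = table.labels.to_numpy()
    tset = ImputationSet(method="mean_replacement", tables=[table])
    for var in ("piq", "spelling", "elision", "digit_span"):
        res = pooled_anova(tset, labels, var)
        assert res["p"] < 1e-6
        for worse in ("PoorDecoder", "PoorComprehender", "GenerallyPoorReader"):
            assert f"Control>{worse}" in res["pairwise"]


def test_anova_d1_pooling_agrees_with_f_for_clear_effects():
    """The multivariate (D1) combination rule detects the same strong
    group effect the mean-F summary does."""
    rng = np.random.default_rng(8)
    tables = []
    n = 60
    labels = np.array(["Control"] * 20 + ["PoorDecoder"] * 20 + ["PoorComprehender"] * 20)
    shifts = {"Control": 15.0, "PoorDecoder": 0.0, "PoorComprehender": -15.0}
    for _ in range(4):
        t = make_small_table(n=n, seed=8)
        t.df["ran"] = rng.normal(100, 10, n) + np.array([shifts[l] for l in labels])
        tables.append(t)
    tset = ImputationSet(method="pmm", tables=tables)
    res = pooled_anova(tset, labels, "ran", method="d1")
    assert res["p"] < 1e-6
    assert res["D1_p"] < 1e-4
    assert res["D1"] > 0


def test_pooled_profile_means_reduce_to_group_means(training_cohort):
    labels = training_cohort.labels.to_numpy()
    single = ImputationSet(method="mean_replacement", tables=[training_cohort])
    out = pooled_profile_means(single, labels)
    row = out[(out.profile == "Control") & (out.variable == "ran")].iloc[0]
    vals = training_cohort.df.loc[labels == "Control", "ran"]
    assert row["mean"] == pytest.approx(vals.mean())
    assert row["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    ident = ImputationSet(method="missforest", tables=[training_cohort] * 5)
    out5 = pooled_profile_means(ident, labels)
    row5 = out5[(out5.profile == "Control") & (out5.variable == "ran")].iloc[0]
    assert row5["sem"] == pytest.approx(row["sem"])
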