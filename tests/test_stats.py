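import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alphaconn.stats import (
    AnovaSpec,
    bh_fdr,
    compare_correlations_fisher,
    corr_test,
    duncan_posthoc,
    edge_group_compare,
    pvalue_from_r,
    rm_anova,
)
from anova_oracle import split_plot_oracle


# ---------------------------------------------------------------- rm_anova
def test_one_way_hand_computation():
    df = pd.DataFrame({"subject": [f"s{i}" for i in range(6)],
                       "g": ["a"] * 3 + ["b"] * 3,
                       "value": [1.0, 2, 3, 4, 5, 6]})
    res = rm_anova(df, AnovaSpec(response="value", between=["g"])).set_index("effect")
    assert res.loc["g", "F"] == pytest.approx(13.5, abs=1e-10)
    assert res.loc["g", "df1"] == 1
    assert res.loc["g", "df2"] == 4


def test_constant_response_gives_zero_f(split_plot_factory):
    df = split_plot_factory(np.random.default_rng(0), n_per_cell=3)
    df["value"] = 5.0
    res = rm_anova(df, AnovaSpec(response="value",
                                 between=["genotype", "age_group"], within=["band"]))
    effects = res[~res["effect"].str.startswith("error")]
    assert np.allclose(effects["F"].fillna(0), 0.0)


def test_between_f_invariant_to_subject_relabeling(split_plot_factory):
    rng = np.random.default_rng(1)
    df = split_plot_factory(rng, n_per_cell=4)
    spec = AnovaSpec(response="value", between=["genotype", "age_group"], within=["band"])
    f1 = rm_anova(df, spec).set_index("effect").loc["genotype", "F"]
    # swap two subject ids within the same between cell
    swap = {"s000": "s001", "s001": "s000"}
    df2 = df.assign(subject=df["subject"].map(lambda s: swap.get(s, s)))
    f2 = rm_anova(df2, spec).set_index("effect").loc["genotype", "F"]
    assert f1 == pytest.approx(f2, rel=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_split_plot_matches_cell_mean_oracle(split_plot_factory, seed):
    """GLM implementation agrees with classical cell-mean arithmetic."""
    rng = np.random.default_rng(seed)
    df = split_plot_factory(rng, n_per_cell=3, effects={"genotype": 0.4, "band": 0.2})
    got = rm_anova(df, AnovaSpec(response="value",
                                 between=["genotype", "age_group"],
                                 within=["band"])).set_index("effect")
    want = split_plot_oracle(df, "genotype", "age_group", "band").set_index("effect")
    for effect in want.index:
        assert got.loc[effect, "F"] == pytest.approx(want.loc[effect, "F"], abs=1e-8)
        assert got.loc[effect, "ss"] == pytest.approx(want.loc[effect, "ss"], abs=1e-8)
        assert got.loc[effect, "df2"] == want.loc[effect, "df2"]


def test_matches_pingouin_mixed_anova():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    rows = []
    for si in range(16):
        g = "a" if si < 8 else "b"
        base = rng.normal()
        for w in range(4):
            rows.append((f"s{si}", g, f"w{w}", base + 0.3 * w + rng.normal()))
    df = pd.DataFrame(rows, columns=["subject", "g", "w", "value"])
    got = rm_anova(df, AnovaSpec(response="value", between=["g"], within=["w"]))
    got = got.set_index("effect")
    want = pg.mixed_anova(df, dv="value", within="w", subject="subject", between="g")
    want = want.set_index("Source")
    assert got.loc["g", "F"] == pytest.approx(want.loc["g", "F"], rel=1e-9)
    assert got.loc["w", "F"] == pytest.approx(want.loc["w", "F"], rel=1e-9)
    assert got.loc["w:g", "F"] == pytest.approx(want.loc["Interaction", "F"], rel=1e-9)


def test_covariate_consumes_between_df(split_plot_factory):
    rng = np.random.default_rng(4)
    df = split_plot_factory(rng, n_per_cell=4)
    sex = {s: rng.integers(0, 2) for s in df["subject"].unique()}
    df["sex"] = df["subject"].map(sex).astype(float)
    spec = AnovaSpec(response="value", between=["genotype", "age_group"],
                     within=["band"], covariates=["sex"])
    res = rm_anova(df, spec).set_index("effect")
    assert "sex" in res.index
    assert res.loc["genotype", "df2"] == 16 - 5  # N - (intercept + sex + 3 effects)


def test_unbalanced_design_errors():
    df = pd.DataFrame({"subject": ["s1", "s1", "s2"], "g": ["a", "a", "b"],
                       "w": ["w1", "w2", "w1"], "value": [1.0, 2, 3]})
    with pytest.raises(ValueError, match="complete"):
        rm_anova(df, AnovaSpec(response="value", between=["g"], within=["w"]))


def test_singleton_group_rejected():
    df = pd.DataFrame({"subject": ["s1", "s2", "s3"], "g": ["a", "a", "b"],
                       "value": [1.0, 2, 3]})
    with pytest.raises(ValueError, match="at least 2"):
        rm_anova(df, AnovaSpec(response="value", between=["g"]))


# ---------------------------------------------------------------- Duncan
def test_duncan_identical_means():
    res = duncan_posthoc({"a": 1.0, "b": 1.0, "c": 1.0},
                         {"a": 5, "b": 5, "c": 5}, ms_error=1.0, df_error=12)
    assert not res["significant"].any()


def test_duncan_two_cells_matches_studentized_range_t_identity():
    """For two means Duncan reduces to |t| > q_{.05}(2, df) / sqrt(2)."""
    ms, df_err, n = 2.0, 20, 8
    for diff in (0.5, 1.0, 1.5, 2.0):
        res = duncan_posthoc({"a": 0.0, "b": diff}, {"a": n, "b": n}, ms, df_err)
        t_stat = diff / np.sqrt(2 * ms / n)
        q_crit = sps.studentized_range.ppf(0.95, 2, df_err)
        assert bool(res["significant"].iloc[0]) == (t_stat > q_crit / np.sqrt(2))


def test_duncan_large_separation_all_significant():
    ms, nh = 1.0, 10
    sep = 10 * np.sqrt(ms / nh)
    means = {f"c{i}": i * sep for i in range(4)}
    res = duncan_posthoc(means, {k: nh for k in means}, ms, df_error=36)
    assert res["significant"].all()


def test_duncan_protection_blocks_inner_pairs():
    # outer range non-significant -> inner pairs cannot be declared significant
    res = duncan_posthoc({"a": 0.0, "b": 0.4, "c": 0.5},
                         {"a": 4, "b": 4, "c": 4}, ms_error=1.0, df_error=9)
    res = res.set_index(["level_a", "level_b"])
    if not res.loc[("a", "c"), "significant"]:
        assert not res.loc[("a", "b"), "significant"]
        assert not res.loc[("b", "c"), "significant"]


def test_duncan_rejects_bad_ms():
    with pytest.raises(ValueError):
        duncan_posthoc({"a": 0, "b": 1}, {"a": 3, "b": 3}, ms_error=0.0, df_error=5)


# ---------------------------------------------------------------- correlations
def test_pvalues_from_printed_correlations():
    assert pvalue_from_r(-0.21, 91) == pytest.approx(0.046, abs=5e-4)
    assert pvalue_from_r(-0.42, 37) == pytest.approx(0.01, abs=5e-4)
    assert pvalue_from_r(0.0, 30) == pytest.approx(1.0)


def test_corr_test_matches_scipy():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(40)
    y = 0.5 * x + rng.standard_normal(40)
    res = corr_test(x, y, method="pearson")
    r_sp, p_sp = sps.pearsonr(x, y)
    assert res.r == pytest.approx(r_sp, abs=1e-12)
    assert res.p == pytest.approx(p_sp, rel=1e-6)
    res_s = corr_test(x, y, method="spearman")
    assert res_s.r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


def test_normality_gate_switches_to_spearman():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(50)
    y = np.exp(rng.standard_normal(50) * 2)  # heavily skewed
    assert corr_test(x, y, method="auto").method == "spearman"
    z = rng.standard_normal(50)
    assert corr_test(x, z, method="auto").method == "pearson"


def test_corr_test_rejects_degenerate_input():
    with pytest.raises(ValueError):
        corr_test(np.ones(10), np.arange(10.0))


def test_fisher_comparison_printed_example():
    z, p = compare_correlations_fisher(-0.49, 46, -0.21, 91, alternative="less")
    assert 0.041 <= p <= 0.043
    z2, p2 = compare_correlations_fisher(0.3, 50, 0.3, 50, alternative="less")
    assert p2 == pytest.approx(0.5)
    z3, p3 = compare_correlations_fisher(0.6, 50, 0.2, 50, alternative="greater")
    assert z3 == pytest.approx(2.38, abs=0.01)
    assert p3 == pytest.approx(0.0087, abs=5e-4)


@given(st.floats(-0.9, 0.9), st.floats(-0.9, 0.9),
       st.integers(5, 200), st.integers(5, 200))
@settings(deadline=None)
def test_fisher_comparison_antisymmetric(r1, r2, n1, n2):
    z_a, _ = compare_correlations_fisher(r1, n1, r2, n2)
    z_b, _ = compare_correlations_fisher(r2, n2, r1, n1)
    assert z_a == pytest.approx(-z_b, abs=1e-12)


# ---------------------------------------------------------------- FDR / edges
def test_bh_hand_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([0.5]), [0.5])
    np.testing.assert_allclose(bh_fdr([0.001, 0.5]), [0.002, 0.5])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
@settings(deadline=None)
def test_bh_order_invariance(pvals):
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(pvals))
    direct = bh_fdr(pvals)
    shuffled = bh_fdr(np.asarray(pvals)[perm])
    np.testing.assert_allclose(np.sort(direct), np.sort(shuffled), atol=1e-12)


def _z_matrices(rng, n_subj, labels, planted=None):
    out = {}
    for i in range(n_subj):
        z = rng.standard_normal((len(labels), len(labels))) * 0.1
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        if planted:
            (a, b), v = planted
            ia, ib = labels.index(a), labels.index(b)
            z[ia, ib] = z[ib, ia] = z[ia, ib] + v
        out[f"s{i}"] = pd.DataFrame(z, index=labels, columns=labels)
    return out


def test_identical_groups_give_null_contrast():
    rng = np.random.default_rng(10)
    labels = list("abcde")
    mats = _z_matrices(rng, 6, labels)
    z_all = {}
    groups = {}
    for i, (k, v) in enumerate(mats.items()):
        z_all[f"ga_{k}"] = v
        z_all[f"gb_{k}"] = v.copy()
        groups[f"ga_{k}"] = "A"
        groups[f"gb_{k}"] = "B"
    res = edge_group_compare(z_all, groups, "A", "B")
    assert np.allclose(res["beta"], 0.0)
    assert not (res["p_fdr"] < 0.05).any()


def test_planted_group_difference_ranks_first():
    rng = np.random.default_rng(11)
    labels = list("abcdefgh")
    za = _z_matrices(rng, 14, labels, planted=(("a", "b"), 0.6))
    zb = _z_matrices(np.random.default_rng(12), 23, labels)
    z_all = {f"p{k}": v for k, v in za.items()} | {f"m{k}": v for k, v in zb.items()}
    groups = {k: ("E4plus" if k.startswith("p") else "E4minus") for k in z_all}
    res = edge_group_compare(z_all, groups, "E4plus", "E4minus")
    assert {res.iloc[0]["roi_i"], res.iloc[0]["roi_j"]} == {"a", "b"}
    assert (res["p_fdr"] >= res["p_unc"] - 1e-15).all()
    assert res["p_unc"].is_monotonic_increasing


def test_small_group_rejected():
    rng = np.random.default_rng(13)
    mats = _z_matrices(rng, 3, list("abc"))
    groups = {"s0": "A", "s1": "B", "s2": "B"}
    with pytest.raises(ValueError):
        edge_group_compare(mats, groups, "A", "B")
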