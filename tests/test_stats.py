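"""Statistical battery: closed forms, enumeration oracles, library cross-checks."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from perturbwalk import stats as st
from perturbwalk.synthetic import PerturbationResponseParams, simulate_mos_table


# --- mixed ANOVA ---


def _cohort(seed, n1=8, n2=12, resp1=None, resp2=None, pert=2):
    resp1 = resp1 or PerturbationResponseParams.faller()
    resp2 = resp2 or PerturbationResponseParams.non_faller()
    return simulate_mos_table(n1, n2, resp1, resp2, pert_index=pert, seed=seed)


def test_mixed_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    df = _cohort(5)
    mine = st.mixed_anova(df)
    ref = pg.mixed_anova(
        data=df, dv="mos", within="step", between="group",
        subject="participant", correction=False,
    ).set_index("Source")
    for ours, theirs in (("group", "group"), ("step", "step"),
                         ("interaction", "Interaction")):
        assert mine.effect(ours)["F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
        assert mine.effect(ours)["p"] == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)
        assert mine.effect(ours)["SS"] == pytest.approx(ref.loc[theirs, "SS"], rel=1e-9)


def test_sums_of_squares_partition_exactly():
    df = _cohort(11, n1=5, n2=7)
    part = st.mixed_anova(df).ss_partition
    parts = (
        part["group"] + part["error_between"] + part["step"]
        + part["interaction"] + part["error_within"]
    )
    assert parts == pytest.approx(part["total"], abs=1e-10 * max(part["total"], 1))


def test_mixed_anova_degenerate_constant_data():
    rows = []
    for g, n in (("Falls", 3), ("NoFalls", 3)):
        for i in range(n):
            for step in ["Base", "Pre", "Post1"]:
                rows.append({"participant": f"{g}{i}", "group": g,
                             "step": step, "mos": 0.05})
    res = st.mixed_anova(pd.DataFrame(rows))
    assert res.degenerate
    assert np.isnan(res.effect("interaction")["F"])


def test_mixed_anova_rejects_missing_cells():
    df = _cohort(3).iloc[:-1]
    with pytest.raises(ValueError, match="missing"):
        st.mixed_anova(df)


def test_interaction_power_with_group_difference():
    """Groups differing in recovery delay produce a detectable interaction."""
    slow = PerturbationResponseParams(delay_steps=2, response_sd=0.01,
                                      adaptation_rate=0.0)
    fast = PerturbationResponseParams(delay_steps=0, response_sd=0.01,
                                      adaptation_rate=0.0)
    hits = 0
    for i in range(40):
        df = simulate_mos_table(10, 10, slow, fast, pert_index=1, seed=300 + i)
        if st.mixed_anova(df).effect("interaction")["p"] < 0.05:
            hits += 1
    assert hits >= 32  # >= 80%


def test_gg_correction_reduces_dfs():
    df = _cohort(7)
    res = st.mixed_anova(df, correction=True)
    assert res.sphericity_correction == "GG"
    assert res.gg_epsilon <= 1.0
    assert res.effect("step")["df1"] <= 9.0


# --- Mann-Whitney ---


def test_mwu_complete_separation():
    u, p = st.mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0


def test_mwu_tied_singletons():
    u, _ = st.mann_whitney_u([1.0], [1.0])
    assert u == 0.5


def _mwu_brute_force_p(x, y):
    """Oracle: direct pair counting per labeling (no rank formula)."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return min(gt, len(xs) * len(ys) - gt)

    obs = u_of(range(n))
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if u_of(idx) <= obs + 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mwu_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 9, size=5).astype(float)  # tied integers
    y = rng.integers(0, 9, size=6).astype(float)
    _, p = st.mann_whitney_u(x, y)
    assert p == pytest.approx(_mwu_brute_force_p(x, y), abs=1e-12)


def test_mwu_empty_rejected():
    with pytest.raises(ValueError):
        st.mann_whitney_u([], [1.0])


def test_mwu_monotone_transform_invariance():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=6), rng.normal(size=7)
    u1, p1 = st.mann_whitney_u(x, y)
    u2, p2 = st.mann_whitney_u(np.exp(x), np.exp(y))
    assert u1 == u2 and p1 == pytest.approx(p2, abs=1e-12)


# --- Wilcoxon ---


def test_wilcoxon_shifted_pairs_one_sided():
    x = np.arange(8.0)
    res = st.wilcoxon_signed_rank(x + 1.0, x, alternative="greater")
    assert res.p == pytest.approx(1.0 / 256.0)


def test_wilcoxon_identical_pairs_degenerate():
    x = np.arange(5.0)
    res = st.wilcoxon_signed_rank(x, x)
    assert res.degenerate and res.p == 1.0


def _wilcoxon_brute_force_p(d):
    """Oracle: enumerate sign patterns, summing |d| directly (midranks)."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    obs = min(r[d > 0].sum(), r[d < 0].sum())
    n = len(d)
    hits = 0
    for mask in range(2 ** n):
        signs = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        wp = r[signs].sum()
        if min(wp, r.sum() - wp) <= obs + 1e-9:
            hits += 1
    return hits / 2 ** n


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wilcoxon_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(-4, 5, size=9).astype(float)
    d[d == 0] = 1.0  # keep all pairs informative, ties among |d| remain
    res = st.wilcoxon_signed_rank(d)
    assert res.p == pytest.approx(_wilcoxon_brute_force_p(d), abs=1e-12)


def test_wilcoxon_no_ties_matches_scipy_exact():
    from scipy.stats import wilcoxon as sw

    rng = np.random.default_rng(8)
    d = rng.normal(size=12)
    res = st.wilcoxon_signed_rank(d)
    assert res.p == pytest.approx(sw(d, method="exact").pvalue, abs=1e-12)


# --- Friedman ---


def test_friedman_perfect_rankings_closed_form():
    # 12 blocks, identical rankings over 3 conditions: chi2 = 24 (maximal)
    tbl = np.tile([1.0, 2.0, 3.0], (12, 1))
    stat, p = st.friedman(tbl)
    assert stat == pytest.approx(24.0)
    assert p < 1e-4


def test_friedman_matches_scipy_for_three_plus_conditions():
    from scipy.stats import friedmanchisquare

    rng = np.random.default_rng(5)
    for k in (3, 4, 5):
        tbl = rng.integers(0, 6, size=(9, k)).astype(float)  # with ties
        stat, p = st.friedman(tbl)
        ref = friedmanchisquare(*(tbl[:, j] for j in range(k)))
        assert stat == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_friedman_two_conditions_reduces_to_sign_test():
    rng = np.random.default_rng(2)
    a = rng.normal(size=14)
    b = a + rng.normal(size=14)
    stat, _ = st.friedman(np.column_stack([a, b]))
    # k=2, no within-block ties: chi2 = (n_plus - n_minus)^2 / n
    s = np.sign(b - a)
    expected = (s.sum()) ** 2 / len(a)
    assert stat == pytest.approx(expected, abs=1e-9)


def test_friedman_null_calibration():
    rng = np.random.default_rng(1)
    rej = 0
    n_rep = 400
    for _ in range(n_rep):
        tbl = rng.normal(size=(10, 3))
        _, p = st.friedman(tbl)
        rej += p < 0.05
    # rejection rate within the binomial 95% band around alpha
    # (Friedman's chi-square null is discrete and conservative at n=10)
    band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
    assert rej / n_rep < 0.05 + band


def test_friedman_incomplete_blocks_rejected():
    tbl = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0]])
    with pytest.raises(ValueError, match="incomplete"):
        st.friedman(tbl)


# --- Dunnett / Sidak ---


def test_dunnett_single_comparison_equals_paired_t():
    from scipy.stats import ttest_rel

    rng = np.random.default_rng(6)
    base = rng.normal(size=10)
    post = base + rng.normal(0.3, 1.0, 10)
    df = pd.DataFrame({"Base": base, "Post1": post})
    res = st.dunnett_vs_control(df, "Base")
    ref = ttest_rel(post, base).pvalue
    assert res.loc["Post1 - Base", "p_adjusted"] == pytest.approx(ref, rel=1e-9)


def test_dunnett_null_adjusted_p_near_one():
    rng = np.random.default_rng(7)
    base = rng.normal(size=12)
    df = pd.DataFrame({"Base": base})
    for j in range(9):
        df[f"Post{j+1}"] = base + rng.normal(0, 1e-6, 12)
    # identical data up to noise: all adjusted p should be large
    df2 = pd.DataFrame({c: rng.normal(size=12) * 0 + 1.0 for c in df.columns})
    df2 += rng.normal(0, 1.0, df2.shape)
    res = st.dunnett_vs_control(df2, "Base", n_sim=20_000, seed=1)
    assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()


def test_dunnett_adjusted_at_least_unadjusted():
    rng = np.random.default_rng(9)
    for trial in range(5):
        df = pd.DataFrame(rng.normal(size=(8, 5)),
                          columns=["Base", "A", "B", "C", "D"])
        res = st.dunnett_vs_control(df, "Base", n_sim=20_000, seed=trial)
        assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()


def test_dunnett_missing_control_rejected():
    with pytest.raises(ValueError, match="control"):
        st.dunnett_vs_control(pd.DataFrame({"A": [1.0, 2.0]}), "Base")


def test_sidak_closed_form_and_identity():
    assert st.sidak_adjust([0.0])[0] == 0.0
    assert st.sidak_adjust([0.05], k=10)[0] == pytest.approx(1 - 0.95 ** 10)
    assert st.sidak_adjust([0.3], k=1)[0] == pytest.approx(0.3)
    with pytest.raises(ValueError):
        st.sidak_adjust([1.2])


# --- effect size / sample size ---


def test_cohens_f_d_conversion():
    assert st.cohens_f_to_d(0.5) == 1.0
    assert st.cohens_f_to_d(0.0) == 0.0
    assert st.cohens_d_to_f(st.cohens_f_to_d(0.37)) == pytest.approx(0.37)
    with pytest.raises(ValueError):
        st.cohens_f_to_d(-0.1)


def test_sample_size_matches_noncentral_t_oracle():
    sm = pytest.importorskip("statsmodels.stats.power")
    n, achieved = st.sample_size_rm_between(
        0.5, alpha=0.05, power=0.8, n_groups=2, n_measures=1, rho=0.0
    )
    per_group = sm.TTestIndPower().solve_power(
        effect_size=1.0, alpha=0.05, power=0.8
    )
    assert n == 2 * int(np.ceil(per_group))
    assert achieved >= 0.8


def test_sample_size_nonincreasing_in_efficiency():
    prev = None
    for rho in (0.9, 0.6, 0.3, 0.0):
        n, _ = st.sample_size_rm_between(0.25, n_measures=10, rho=rho)
        if prev is not None:
            assert n <= prev
        prev = n


def test_sample_size_rho_one_limit_matches_single_measure():
    n_multi, _ = st.sample_size_rm_between(0.4, n_measures=10, rho=1 - 1e-9)
    n_single, _ = st.sample_size_rm_between(0.4, n_measures=1, rho=0.0)
    assert n_multi == n_single
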