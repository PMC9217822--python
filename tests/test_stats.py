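"""Nonparametric group comparisons, correlations, ANCOVA and categorical tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from micrographia.stats import (
    GroupedMetric,
    kruskal_wallis,
    dunn_pairwise,
    spearman_rho,
    relative_median_difference,
    ancova_group_contrast,
    categorical_test,
)


def gm(**groups):
    return GroupedMetric("m", {k: np.asarray(v, dtype=float) for k, v in groups.items()})


# -- Kruskal-Wallis ----------------------------------------------------------

def test_kw_perfect_separation_three_groups():
    """H reaches its n=(3,3,3) maximum 7.2 under complete separation."""
    res = kruskal_wallis(gm(a=[1, 2, 3], b=[4, 5, 6], c=[7, 8, 9]))
    assert res.statistic == pytest.approx(7.2)


def test_kw_exchangeable_groups_small_h():
    res = kruskal_wallis(gm(a=[1, 2, 3], b=[1, 2, 3], c=[1, 2, 3]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value > 0.9


def test_kw_all_identical_degenerates_to_null():
    res = kruskal_wallis(gm(a=[5, 5], b=[5, 5, 5]))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kw_two_groups_exact_permutation_oracle():
    """H for {1,2} vs {3,4} checked against all 6 equal-probable labelings."""
    res = kruskal_wallis(gm(a=[1, 2], b=[3, 4]))
    values = [1, 2, 3, 4]
    hs = []
    for pos_a in itertools.combinations(range(4), 2):
        a = [values[i] for i in pos_a]
        b = [values[i] for i in range(4) if i not in pos_a]
        hs.append(ss.kruskal(a, b)[0])
    assert res.statistic == pytest.approx(max(hs))
    exact_p = np.mean([h >= res.statistic - 1e-9 for h in hs])
    assert exact_p == pytest.approx(1 / 3)  # two extreme labelings of six


def test_kw_invariant_under_monotone_transform():
    base = gm(a=[1, 2, 3], b=[2.5, 6, 7], c=[0.5, 8, 9])
    transformed = GroupedMetric("m", {k: np.exp(v) for k, v in base.groups.items()})
    assert kruskal_wallis(base).statistic == pytest.approx(
        kruskal_wallis(transformed).statistic
    )


# -- Dunn pairwise -----------------------------------------------------------

def _dunn_oracle(groups: dict[str, np.ndarray]):
    """Independent direct evaluation of the tie-corrected rank-mean z formula."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = pooled.size
    ranks = ss.rankdata(pooled)
    splits = np.split(ranks, np.cumsum([groups[k].size for k in labels])[:-1])
    mean_rank = dict(zip(labels, (s.mean() for s in splits)))
    _, t = np.unique(pooled, return_counts=True)
    var = n * (n + 1) / 12 - (t**3 - t).sum() / (12 * (n - 1))
    out = {}
    for i, j in itertools.combinations(labels, 2):
        se = math.sqrt(var * (1 / groups[i].size + 1 / groups[j].size))
        out[(i, j)] = (mean_rank[i] - mean_rank[j]) / se
    return out


def test_dunn_matches_direct_rank_mean_formula():
    groups = {
        "a": np.array([3.1, 1.2, 5.0, 4.4]),
        "b": np.array([2.2, 6.7, 8.1]),
        "c": np.array([7.7, 9.3, 10.0]),
    }
    oracle = _dunn_oracle(groups)
    for t in dunn_pairwise(GroupedMetric("m", groups)):
        assert t.z == pytest.approx(oracle[t.pair], abs=1e-12)
        assert 0.0 <= t.p_adjusted <= 1.0


def test_dunn_with_ties_matches_oracle():
    groups = {
        "a": np.array([1.0, 2.0, 2.0, 3.0]),
        "b": np.array([2.0, 4.0, 5.0]),
        "c": np.array([5.0, 5.0, 6.0]),
    }
    oracle = _dunn_oracle(groups)
    for t in dunn_pairwise(GroupedMetric("m", groups)):
        assert t.z == pytest.approx(oracle[t.pair], abs=1e-12)


def test_dunn_identical_groups_zero_z_unit_p():
    res = dunn_pairwise(gm(a=[1, 2, 3], b=[1, 2, 3], c=[9, 10, 11]))
    ab = next(t for t in res if t.pair == ("a", "b"))
    assert ab.z == pytest.approx(0.0, abs=1e-12)
    assert ab.p_adjusted == 1.0


def test_dunn_antisymmetric_under_group_swap():
    g1 = gm(a=[1, 2, 3], b=[4, 5, 6], c=[2, 3, 9])
    g2 = gm(b=[4, 5, 6], a=[1, 2, 3], c=[2, 3, 9])
    z1 = {t.pair: t.z for t in dunn_pairwise(g1)}
    z2 = {t.pair: t.z for t in dunn_pairwise(g2)}
    assert z1[("a", "b")] == pytest.approx(-z2[("b", "a")])


# -- Spearman ----------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
    assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_with_tie_matches_midrank_pearson():
    x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 6.0])
    rho, _ = spearman_rho(x, y)
    oracle = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_constant_input_undefined():
    rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_invariant_under_increasing_transform():
    x = np.array([0.3, 1.7, 0.9, 2.4, 3.3, 0.1])
    y = np.array([5.0, 2.0, 4.4, 1.2, 0.7, 6.0])
    assert spearman_rho(np.exp(x), y)[0] == pytest.approx(spearman_rho(x, y)[0])


# -- relative median difference ---------------------------------------------

def test_relative_median_difference_published_letter_height():
    """Medians 4.3 vs 5.0 mm: the PD group writes 14.0% smaller letters."""
    m = gm(PD=[4.3], ET=[5.0])
    assert relative_median_difference(m, "PD", "ET") == pytest.approx(14.0)


def test_relative_median_difference_published_area():
    m = gm(PD=[399.0], ET=[536.0])
    assert round(relative_median_difference(m, "PD", "ET"), 1) == 25.6


def test_relative_median_difference_equal_medians_zero():
    m = gm(PD=[3, 4, 5], ET=[2, 4, 8])
    assert relative_median_difference(m, "PD", "ET") == pytest.approx(0.0)


def test_relative_median_difference_scale_invariant():
    a, b = [2.0, 3.0, 7.0], [4.0, 5.0, 6.0]
    v1 = relative_median_difference(gm(PD=a, ET=b), "PD", "ET")
    v2 = relative_median_difference(
        gm(PD=[x * 13.7 for x in a], ET=[x * 13.7 for x in b]), "PD", "ET"
    )
    assert v1 == pytest.approx(v2)


def test_relative_median_difference_zero_reference_errors():
    with pytest.raises(ValueError, match="zero"):
        relative_median_difference(gm(PD=[1.0], ET=[0.0]), "PD", "ET")


# -- ANCOVA ------------------------------------------------------------------

def _covariates(rng, n):
    return pd.DataFrame({
        "age": rng.normal(66, 10, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "mmse": rng.normal(28, 2, n),
        "updrs3": rng.normal(30, 12, n),
    })


def test_ancova_recovers_known_group_effect(rng):
    n, delta = 400, 0.8
    covs = _covariates(rng, n)
    g = rng.integers(0, 2, n)
    y = delta * g + 0.02 * covs["age"].to_numpy() + rng.normal(0, 0.5, n)
    res = ancova_group_contrast(y, g, covs)
    assert res.adjusted_difference == pytest.approx(delta, abs=0.15)
    assert res.p_value < 1e-6


def test_ancova_saturated_group_indicator(rng):
    """Outcome exactly equal to the group flag: residual variance ~ 0."""
    n = 50
    covs = _covariates(rng, n)
    g = rng.integers(0, 2, n)
    res = ancova_group_contrast(g.astype(float), g, covs)
    assert res.adjusted_difference == pytest.approx(1.0, abs=1e-8)


def test_ancova_collinear_design_named(rng):
    n = 50
    covs = _covariates(rng, n)
    covs["age_copy"] = covs["age"]
    g = rng.integers(0, 2, n)
    with pytest.raises(ValueError, match="collinear"):
        ancova_group_contrast(rng.normal(size=n), g, covs)


def test_ancova_drops_incomplete_cases(rng):
    n = 80
    covs = _covariates(rng, n)
    covs.loc[covs.index[:5], "mmse"] = np.nan
    res = ancova_group_contrast(rng.normal(size=n), rng.integers(0, 2, n), covs)
    assert res.n_used == n - 5 and res.n_dropped == 5


# -- categorical tests -------------------------------------------------------

def test_categorical_balanced_2x2_unit_p():
    stat, p, method = categorical_test(np.array([[8, 8], [8, 8]]))
    assert p == pytest.approx(1.0)
    assert method == "chi-square"


def test_categorical_sparse_2x2_uses_exact_hypergeometric():
    """Table (5,0;0,5): two-sided Fisher p equals 2/C(10,5) by enumeration."""
    stat, p, method = categorical_test(np.array([[5, 0], [0, 5]]))
    assert method == "fisher-exact"
    # enumeration over the hypergeometric support with margins (5,5)/(5,5)
    probs = [ss.hypergeom.pmf(k, 10, 5, 5) for k in range(6)]
    p_obs = probs[5]
    expected = sum(pr for pr in probs if pr <= p_obs + 1e-12)
    assert p == pytest.approx(expected)
    assert p == pytest.approx(2 / 252)


def test_categorical_large_table_uses_chi_square():
    table = np.array([[30, 40, 20], [25, 35, 30], [40, 20, 30]])
    _, p, method = categorical_test(table)
    assert method == "chi-square"
    assert 0 <= p <= 1


def test_categorical_null_calibration(rng):
    """Chi-square p approximately uniform under independence."""
    ps = []
    for _ in range(300):
        r = rng.multinomial(200, np.ones(6) / 6).reshape(2, 3)
        if (r.sum(axis=1) > 0).all() and (r.sum(axis=0) > 0).all():
            ps.append(categorical_test(r)[1])
    # Kolmogorov-Smirnov against uniform; generous bound for discreteness
    d = ss.kstest(ps, "uniform").statistic
    assert d < 0.12


def test_categorical_empty_table_errors():
    with pytest.raises(ValueError):
        categorical_test(np.zeros((2, 2)))
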