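"""Group-comparison and correlation statistics for the three-group cohort.

Continuous variables are compared across PD / ET / HC with the tie-corrected
Kruskal–Wallis test; significant omnibus results are followed by Dunn pairwise
rank tests with Bonferroni correction over the pairs within each variable.
Categorical variables use Pearson chi-square, or Fisher's exact test when
expected counts are too small.  Monotone associations use Spearman's rho.
Group contrasts adjusted for age, sex, cognition and motor severity use
ANCOVA (an ordinary linear model with the group indicator tested).

All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm

__all__ = [
    "GroupedMetric",
    "PairwiseTest",
    "ComparisonResult",
    "kruskal_wallis",
    "dunn_pairwise",
    "compare_groups",
    "spearman_rho",
    "relative_median_difference",
    "ancova_group_contrast",
    "categorical_test",
]


@dataclass
class GroupedMetric:
    """One numeric variable split by group label (e.g. PD / ET / HC)."""

    metric_name: str
    groups: dict[str, np.ndarray]  # label -> finite values (missing removed)
    n_missing: int = 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str, group_col: str = "group"):
        groups, n_missing = {}, 0
        for label, sub in df.groupby(group_col, sort=False):
            v = sub[value_col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            n_missing += int((~ok).sum())
            if ok.any():
                groups[str(label)] = v[ok]
        return cls(metric_name=value_col, groups=groups, n_missing=n_missing)


@dataclass(frozen=True)
class PairwiseTest:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float  # Bonferroni over the pairs for this variable


@dataclass
class ComparisonResult:
    metric_name: str
    statistic: float            # Kruskal-Wallis H, tie-corrected
    p_value: float
    n_per_group: dict[str, int]
    pairwise: list[PairwiseTest] = field(default_factory=list)
    skipped_pairs: list[str] = field(default_factory=list)


def kruskal_wallis(metric: GroupedMetric) -> ComparisonResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square (k−1 df) p-value.

    All values identical across groups is a degenerate tie pattern and returns
    H = 0, p = 1 rather than failing.
    """
    samples = [v for v in metric.groups.values() if v.size > 0]
    if len(samples) < 2:
        raise ValueError(f"{metric.metric_name}: need >=2 non-empty groups")
    pooled = np.concatenate(samples)
    if pooled.size < 3:
        raise ValueError(f"{metric.metric_name}: need total N >= 3")
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = ss.kruskal(*samples)
    return ComparisonResult(
        metric_name=metric.metric_name,
        statistic=float(h),
        p_value=float(p),
        n_per_group={k: int(v.size) for k, v in metric.groups.items()},
    )


def dunn_pairwise(metric: GroupedMetric) -> list[PairwiseTest]:
    """Dunn rank-based pairwise z tests with Bonferroni adjustment.

    For pair (i, j): z = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1)))
    (1/n_i + 1/n_j)] where R̄ are mean midranks of the pooled sample and
    ΣT = Σ(t³ − t) over tie groups.  Two-sided normal p, multiplied by the
    number of pairs (clipped at 1).
    """
    labels = [k for k, v in metric.groups.items() if v.size > 0]
    if len(labels) < 2:
        raise ValueError(f"{metric.metric_name}: need >=2 non-empty groups")
    values = np.concatenate([metric.groups[k] for k in labels])
    sizes = np.array([metric.groups[k].size for k in labels])
    n_total = values.size
    ranks = ss.rankdata(values)  # midranks
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        k: ranks[bounds[i]: bounds[i + 1]].mean() for i, k in enumerate(labels)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            se = math.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0.0:  # all pooled values tied
                z, p_raw = 0.0, 1.0
            else:
                z = (mean_ranks[la] - mean_ranks[lb]) / se
                p_raw = 2.0 * ss.norm.sf(abs(z))
            out.append(
                PairwiseTest(
                    pair=(la, lb),
                    z=float(z),
                    p_raw=float(p_raw),
                    p_adjusted=float(min(1.0, p_raw * n_pairs)),
                )
            )
    return out


def compare_groups(metric: GroupedMetric) -> ComparisonResult:
    """Omnibus Kruskal–Wallis plus Dunn–Bonferroni pairwise tests."""
    result = kruskal_wallis(metric)
    result.pairwise = dunn_pairwise(metric)
    return result


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation with pairwise missing removal.

    Ties handled by midranks; p-value from the t approximation.  Returns
    (nan, nan) when fewer than 3 complete pairs remain or a rank vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return (math.nan, math.nan)
    rho, p = ss.spearmanr(x, y)
    return (float(rho), float(p))


def relative_median_difference(
    metric: GroupedMetric, group_a: str, group_b: str
) -> float:
    """How much smaller group_a's median is relative to group_b's, in percent.

    100 × (median_b − median_a) / median_b.  Positive when a's median is below
    b's on a positive-valued scale; with a negative reference median the sign
    flips, so report the magnitude for signed metrics such as the b value.
    """
    va, vb = metric.groups.get(group_a), metric.groups.get(group_b)
    if va is None or vb is None or va.size == 0 or vb.size == 0:
        raise ValueError(f"both groups must be non-empty ({group_a}, {group_b})")
    med_a, med_b = float(np.median(va)), float(np.median(vb))
    if med_b == 0.0:
        raise ValueError("reference group median is zero; relative difference undefined")
    return 100.0 * (med_b - med_a) / med_b


@dataclass(frozen=True)
class AncovaResult:
    adjusted_difference: float  # group coefficient (group=1 minus group=0)
    t_statistic: float
    p_value: float
    n_used: int
    n_dropped: int              # listwise deletion over outcome + covariates


def ancova_group_contrast(
    outcome: Sequence[float],
    group_flag: Sequence[int],
    covariates: pd.DataFrame,
) -> AncovaResult:
    """ANCOVA group contrast: outcome ~ group + covariates (OLS, t test on group).

    ``group_flag`` is binary (with/without micrographia); covariates typically
    age, sex (0/1), MMSE and MDS-UPDRS III.  Rows with any missing value are
    dropped listwise.  Raises on a rank-deficient design, naming a collinear
    column.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group_flag, dtype=float)
    X = covariates.to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(g) & np.all(np.isfinite(X), axis=1)
    y, g, X = y[ok], g[ok], X[ok]
    n_terms = X.shape[1] + 2  # intercept + group + covariates
    if y.size <= n_terms + 2:
        raise ValueError(f"too few complete cases ({y.size}) for {n_terms} model terms")
    design = np.column_stack([np.ones_like(y), g, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        names = ["intercept", "group", *covariates.columns]
        for j in range(design.shape[1]):
            keep = np.delete(np.arange(design.shape[1]), j)
            if np.linalg.matrix_rank(design[:, keep]) == np.linalg.matrix_rank(design):
                raise ValueError(f"collinear design: column '{names[j]}' is redundant")
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return AncovaResult(
        adjusted_difference=float(fit.params[1]),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_used=int(y.size),
        n_dropped=int((~ok).sum()),
    )


def categorical_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float, str]:
    """Chi-square or Fisher's exact test for a two-way contingency table.

    Pearson chi-square (no continuity correction) when at least 80% of cells
    have expected counts >= 5; otherwise Fisher's exact test for 2×2 tables.
    Larger sparse tables fall back to chi-square with the method string noting
    the validity caveat.  Returns (statistic, p, method).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.size == 0 or t.sum() == 0:
        raise ValueError("contingency table must be a non-empty 2-D array of counts")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold non-negative integer counts")
    # drop all-zero rows/columns: they carry no information and break expected counts
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table is degenerate after removing empty rows/columns")
    chi2, p, dof, expected = ss.chi2_contingency(t, correction=False)
    if (expected >= 5).mean() >= 0.8:
        return (float(chi2), float(p), "chi-square")
    if t.shape == (2, 2):
        odds, p_exact = ss.fisher_exact(t)
        return (float(odds), float(p_exact), "fisher-exact")
    return (float(chi2), float(p), "chi-square (low expected counts; exact test unavailable for r×c)")
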