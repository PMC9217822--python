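"""Diagnostic accuracy of micrographia metrics for PD versus ET.

Each writing metric is evaluated as a binary classifier separating Parkinson's
disease (the positive/disease class) from essential tremor.  Because patients
with PD write smaller (and with a more negative slope), the default orientation
calls a subject positive when the score is *at or below* a cutoff.  The ROC
curve is traced over the observed score values; the area under it equals the
Mann–Whitney probability P(score_PD < score_ET) + ½ P(tie), with a 95%
confidence interval from the DeLong covariance estimator.  The operating
cutoff maximizes the Youden index J = sensitivity + specificity − 1, breaking
ties toward higher specificity.

The early-disease subgroup filter retains unmedicated subjects with symptom
duration ≤ 24 months, MMSE ≥ 27 and MDS-UPDRS III ≤ 36 (all bounds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss

__all__ = [
    "RocPoint",
    "DiagnosticResult",
    "SubgroupCriteria",
    "roc_curve",
    "auc_mann_whitney",
    "auc_trapezoidal",
    "auc_with_ci",
    "youden_cutoff",
    "apply_subgroup",
    "evaluate_metric",
]

Orientation = Literal["lower", "higher"]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float  # percent, on the PD (disease) class
    specificity: float  # percent, on the ET class


@dataclass
class DiagnosticResult:
    metric_name: str
    orientation: Orientation
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float  # percent at the Youden cutoff
    specificity: float  # percent at the Youden cutoff
    n_pd: int
    n_et: int
    subgroup_label: str = "all"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SubgroupCriteria:
    """Early-disease filter; all bounds inclusive."""

    require_unmedicated: bool = True
    max_duration_months: float = 24.0
    min_mmse: float = 27.0
    max_updrs3: float = 36.0


EARLY_DISEASE = SubgroupCriteria()


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    classes = set(np.unique(labels).tolist())
    if not {"PD", "ET"} <= classes:
        raise ValueError(f"both PD and ET must be present, got classes {sorted(classes)}")
    return scores, labels


def roc_curve(
    scores: Sequence[float], labels: Sequence[str], orientation: Orientation = "lower"
) -> list[RocPoint]:
    """Operating points at every distinct observed score, plus the two extremes.

    With orientation "lower" a subject is called positive (PD) when
    score <= threshold; "higher" flips the call to score >= threshold.
    """
    scores, labels = _validate(np.asarray(scores), np.asarray(labels))
    pd_scores = scores[labels == "PD"]
    et_scores = scores[labels == "ET"]
    points = []
    thresholds = np.unique(scores)
    if orientation == "lower":
        # threshold below the minimum: nobody called positive
        grid = np.concatenate([[-np.inf], thresholds, [np.inf]])
        for t in grid:
            sens = 100.0 * np.mean(pd_scores <= t)
            spec = 100.0 * np.mean(et_scores > t)
            points.append(RocPoint(float(t), float(sens), float(spec)))
    elif orientation == "higher":
        grid = np.concatenate([[np.inf], thresholds[::-1], [-np.inf]])
        for t in grid:
            sens = 100.0 * np.mean(pd_scores >= t)
            spec = 100.0 * np.mean(et_scores < t)
            points.append(RocPoint(float(t), float(sens), float(spec)))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return points


def auc_mann_whitney(
    scores: Sequence[float], labels: Sequence[str], orientation: Orientation = "lower"
) -> float:
    """AUC as the Mann–Whitney pair-count probability.

    With "lower" orientation: P(score_PD < score_ET) + ½ P(score_PD = score_ET)
    over all PD×ET pairs.
    """
    scores, labels = _validate(np.asarray(scores), np.asarray(labels))
    pd_scores = scores[labels == "PD"][:, None]
    et_scores = scores[labels == "ET"][None, :]
    if orientation == "lower":
        wins = (pd_scores < et_scores).sum()
    else:
        wins = (pd_scores > et_scores).sum()
    ties = (pd_scores == et_scores).sum()
    return float((wins + 0.5 * ties) / (pd_scores.size * et_scores.size))


def auc_trapezoidal(points: Sequence[RocPoint]) -> float:
    """AUC by trapezoidal integration of the ROC points in (FPR, TPR) space."""
    fpr = np.array([1.0 - p.specificity / 100.0 for p in points])
    tpr = np.array([p.sensitivity / 100.0 for p in points])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC for scores oriented higher ⇒ positive."""
    m, n = pos.size, neg.size
    # placement values via midranks (handles ties)
    combined = np.concatenate([pos, neg])
    ranks = ss.rankdata(combined)
    pos_ranks, neg_ranks = ranks[:m], ranks[m:]
    v10 = (pos_ranks - ss.rankdata(pos)) / n          # P(neg < pos_i) + ½ties
    v01 = 1.0 - (neg_ranks - ss.rankdata(neg)) / m    # P(pos > neg_j) + ½ties
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[str],
    orientation: Orientation = "lower",
    alpha: float = 0.05,
    ci_method: Literal["delong", "hanley-mcneil"] = "delong",
) -> tuple[float, float, float]:
    """AUC with a two-sided normal-approximation CI (DeLong by default).

    The Hanley–McNeil variance (exponential approximation) is available as an
    alternative.  The CI is clipped to [0, 1] and always brackets the point
    estimate.
    """
    scores, labels = _validate(np.asarray(scores), np.asarray(labels))
    oriented = -scores if orientation == "lower" else scores
    pos = oriented[labels == "PD"]
    neg = oriented[labels == "ET"]
    auc = auc_mann_whitney(scores, labels, orientation)
    if ci_method == "delong":
        var = _delong_variance(pos, neg)
    elif ci_method == "hanley-mcneil":
        m, n = pos.size, neg.size
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = ss.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return (auc, max(0.0, min(auc, auc - half)), min(1.0, max(auc, auc + half)))


def youden_cutoff(points: Sequence[RocPoint]) -> tuple[float, float, float]:
    """(cutoff, sensitivity %, specificity %) maximizing J = sens + spec − 100.

    Ties in J are broken toward the more specific operating point (fewer false
    positives); any residual tie resolves to the earlier point in threshold
    order, making the choice deterministic.
    """
    if not points:
        raise ValueError("empty ROC point set")
    best = None
    for p in points:
        j = p.sensitivity + p.specificity - 100.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and p.specificity > best[1].specificity + 1e-12
        ):
            best = (j, p)
    p = best[1]
    return (p.threshold, p.sensitivity, p.specificity)


def apply_subgroup(
    cohort: pd.DataFrame, criteria: SubgroupCriteria = EARLY_DISEASE
) -> pd.DataFrame:
    """Rows satisfying all early-disease criteria; missing fields exclude a row."""
    needed = ["levodopa", "duration_months", "mmse", "updrs3"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks subgroup columns: {missing_cols}")
    mask = pd.Series(True, index=cohort.index)
    if criteria.require_unmedicated:
        mask &= cohort["levodopa"].eq("no")
    mask &= cohort["duration_months"].le(criteria.max_duration_months)
    mask &= cohort["mmse"].ge(criteria.min_mmse)
    mask &= cohort["updrs3"].le(criteria.max_updrs3)
    mask &= cohort[needed[1:]].notna().all(axis=1)
    return cohort.loc[mask.fillna(False)]


def evaluate_metric(
    scores: Sequence[float],
    labels: Sequence[str],
    metric_name: str,
    orientation: Orientation = "lower",
    subgroup_label: str = "all",
    ci_method: Literal["delong", "hanley-mcneil"] = "delong",
) -> DiagnosticResult:
    """Full ROC / AUC / Youden evaluation of one metric on one subject subset."""
    scores_arr, labels_arr = _validate(np.asarray(scores), np.asarray(labels))
    points = roc_curve(scores_arr, labels_arr, orientation)
    auc, lo, hi = auc_with_ci(scores_arr, labels_arr, orientation, ci_method=ci_method)
    cutoff, sens, spec = youden_cutoff(points)
    return DiagnosticResult(
        metric_name=metric_name,
        orientation=orientation,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_pd=int((labels_arr == "PD").sum()),
        n_et=int((labels_arr == "ET").sum()),
        subgroup_label=subgroup_label,
    )
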