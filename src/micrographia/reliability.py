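"""Interrater reliability: two-way random-effects, absolute-agreement ICC.

Two examiners measure the same writing samples with a ruler; the agreement of
their single ratings is summarized by ICC(2,1) — the two-way random-effects,
single-rating, absolute-agreement intraclass correlation (McGraw & Wong
"Case 2A" single measures).  From the two-way ANOVA mean squares of an
n-subjects × k-raters grid:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

where MSR, MSC and MSE are the subject (row), rater (column) and residual mean
squares.  Absolute agreement penalizes systematic rater offsets, unlike
consistency-type ICCs.  The 95% confidence interval uses the F-distribution
construction of the same framework.  ICC values are interpreted as poor
(< 0.50), moderate (0.50–0.75), good (0.75–0.90) and excellent (> 0.90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

__all__ = ["RatingMatrix", "ICCResult", "icc_2_1", "icc_band", "icc_from_long"]


@dataclass
class RatingMatrix:
    """Complete n_subjects × k_raters grid of one metric's measurements."""

    values: np.ndarray
    metric_name: str = ""
    n_dropped: int = 0  # subjects removed for missing ratings

    @classmethod
    def from_array(cls, values, metric_name: str = "", **kw) -> "RatingMatrix":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("rating grid must be 2-D (subjects × raters)")
        complete = np.all(np.isfinite(arr), axis=1)
        dropped = int((~complete).sum())
        arr = arr[complete]
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(
                f"need >=2 subjects and >=2 raters after dropping incomplete rows "
                f"(got {arr.shape})"
            )
        return cls(values=arr, metric_name=metric_name, n_dropped=dropped, **kw)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n: int
    k: int
    metric_name: str = ""


def icc_band(icc: float) -> str:
    """Interpretation band; boundary values fall in the lower-open band.

    0.50 is moderate (only "below 0.50" is poor), 0.75 is moderate, 0.90 is
    good (only "above 0.90" is excellent).
    """
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_2_1(matrix: RatingMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based 95% confidence interval.

    Raises if the grid has no variance at all (the ICC is then undefined, not
    perfect).
    """
    x = matrix.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if mse == 0.0 and msc == 0.0:
        # raters agree exactly on every subject: degenerate perfect agreement
        lo, hi = 1.0, 1.0
    else:
        # Satterthwaite df for the rater+error combination, then F bounds
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        if math.isinf(a):
            lo, hi = 1.0, 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_l = ss.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = ss.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        band=icc_band(float(icc)),
        n=n,
        k=k,
        metric_name=matrix.metric_name,
    )


def icc_from_long(ratings: pd.DataFrame) -> dict[str, ICCResult]:
    """ICC(2,1) per metric from a long-format ratings table.

    Expects columns subject_id, rater_id, metric_name, value.  Subjects with
    any missing rating for a metric are dropped listwise for that metric.
    """
    required = {"subject_id", "rater_id", "metric_name", "value"}
    if not required <= set(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    out = {}
    for metric, sub in ratings.groupby("metric_name", sort=False):
        wide = sub.pivot(index="subject_id", columns="rater_id", values="value")
        out[str(metric)] = icc_2_1(
            RatingMatrix.from_array(wide.to_numpy(), metric_name=str(metric))
        )
    return out
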