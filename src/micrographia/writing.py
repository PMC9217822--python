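"""Quantification of consistent and progressive micrographia from writing samples.

A subject writes the Finnish sentence "Tänään on kaunis päivä" beneath a drawn
house.  Consistent micrographia (a global reduction in letter size) is measured
as the mean height of the letters "T", "p" and "ä" (umlaut excluded) and as the
writing area (mean letter height × sample width).  Progressive micrographia
(letters shrinking while writing) is the ordinary-least-squares slope, the
*b value*, of the six sequential "a"-class letter heights against their position
1..6.  Subjects are classified against a healthy-control reference: a metric
below the HC mean minus two HC standard deviations is flagged positive.

All lengths are millimetres except the house dimensions (centimetres); the
writing area is mm² and the drawing area cm².  Missing or invalid measurements
propagate as NaN with a recorded exclusion reason rather than being imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WritingSample",
    "MicrographiaProfile",
    "ReferenceThresholds",
    "compute_mean_letter_height",
    "compute_writing_area",
    "compute_progressive_b",
    "compute_drawing_area",
    "compute_profile",
    "derive_reference_thresholds",
    "classify_micrographia",
    "compute_metrics_table",
]

#: abscissa for the six sequential "a"-class letters (unit spacing; the OLS
#: slope is invariant to the index origin)
A_INDEX = np.arange(1.0, 7.0)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _valid_length(x) -> bool:
    """A usable length measurement: present, finite and strictly positive."""
    return not _is_missing(x) and math.isfinite(x) and x > 0


@dataclass
class WritingSample:
    """Raw measurements taken from one subject's writing and drawing sample.

    Any field may be missing (``None`` or NaN); downstream metrics are then
    reported as missing with a reason instead of raising.
    """

    height_T: Optional[float] = None        # mm
    height_p: Optional[float] = None        # mm
    height_a_umlautless: Optional[float] = None  # mm, the "ä" without umlaut
    a_heights: Optional[Sequence[float]] = None  # six heights, mm, writing order
    sample_width: Optional[float] = None    # mm
    house_width: Optional[float] = None     # cm
    house_height: Optional[float] = None    # cm


@dataclass
class MicrographiaProfile:
    """Derived per-subject micrographia measures and classification flags."""

    mean_letter_height: float = math.nan    # mm
    writing_area: float = math.nan          # mm²
    progressive_b: float = math.nan         # mm per letter position
    drawing_area: float = math.nan          # cm²
    consistent_flag: Optional[bool] = None
    progressive_flag: Optional[bool] = None
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReferenceThresholds:
    """−2 SD classification thresholds derived from a healthy-control group."""

    consistent_threshold: float             # mm: HC mean height − 2·SD
    progressive_threshold: float            # slope: HC mean b − 2·SD
    n_reference: int
    reference_group: str = "HC"
    sd_multiplier: float = 2.0


def compute_mean_letter_height(sample: WritingSample) -> float:
    """Arithmetic mean of the heights of "T", "p" and the umlaut-less "ä" (mm).

    Returns NaN if any of the three heights is missing or non-positive,
    mirroring the exclusion of incomplete samples.
    """
    heights = (sample.height_T, sample.height_p, sample.height_a_umlautless)
    if not all(_valid_length(h) for h in heights):
        return math.nan
    return float(sum(heights) / 3.0)


def compute_writing_area(sample: WritingSample) -> float:
    """Writing area (mm²): mean letter height multiplied by the sample width."""
    mean_h = compute_mean_letter_height(sample)
    if math.isnan(mean_h) or not _valid_length(sample.sample_width):
        return math.nan
    return float(mean_h * sample.sample_width)


def compute_progressive_b(a_heights: Sequence[float]) -> float:
    """OLS slope (the *b value*) of the six "a" heights against position 1..6.

    A negative slope means the letters shrink while writing (progressive
    micrographia).  Requires exactly six present, positive heights; otherwise
    NaN.  Closed form: b = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)².
    """
    if a_heights is None:
        return math.nan
    y = np.asarray(list(a_heights), dtype=float)
    if y.size != 6 or not np.all(np.isfinite(y)) or not np.all(y > 0):
        return math.nan
    x = A_INDEX
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def compute_drawing_area(sample: WritingSample) -> float:
    """Drawing area (cm²): width × height of the drawn house."""
    if not (_valid_length(sample.house_width) and _valid_length(sample.house_height)):
        return math.nan
    return float(sample.house_width * sample.house_height)


def compute_profile(sample: WritingSample) -> MicrographiaProfile:
    """Compute all four micrographia metrics for one sample.

    Flags are left unset; :func:`classify_micrographia` fills them once a
    healthy-control reference is available.
    """
    profile = MicrographiaProfile(
        mean_letter_height=compute_mean_letter_height(sample),
        writing_area=compute_writing_area(sample),
        progressive_b=compute_progressive_b(sample.a_heights),
        drawing_area=compute_drawing_area(sample),
    )
    if math.isnan(profile.mean_letter_height):
        profile.exclusion_reasons.append("incomplete letter heights (T, p, ä)")
    if math.isnan(profile.writing_area) and not math.isnan(profile.mean_letter_height):
        profile.exclusion_reasons.append("missing or invalid sample width")
    if math.isnan(profile.progressive_b):
        profile.exclusion_reasons.append("fewer than six valid 'a' heights")
    if math.isnan(profile.drawing_area):
        profile.exclusion_reasons.append("missing house dimensions")
    return profile


def derive_reference_thresholds(
    hc_profiles: Sequence[MicrographiaProfile],
    sd_multiplier: float = 2.0,
    reference_group: str = "HC",
) -> ReferenceThresholds:
    """Mean − ``sd_multiplier``·SD thresholds from healthy-control profiles.

    Uses the sample standard deviation (n−1 denominator).  Requires at least
    two HC profiles with both a mean letter height and a b value.
    """
    heights = np.array([p.mean_letter_height for p in hc_profiles], dtype=float)
    bs = np.array([p.progressive_b for p in hc_profiles], dtype=float)
    heights = heights[np.isfinite(heights)]
    bs = bs[np.isfinite(bs)]
    if heights.size < 2 or bs.size < 2:
        raise ValueError(
            "at least 2 reference subjects with complete metrics are required "
            f"(got {heights.size} heights, {bs.size} b values)"
        )
    return ReferenceThresholds(
        consistent_threshold=float(heights.mean() - sd_multiplier * heights.std(ddof=1)),
        progressive_threshold=float(bs.mean() - sd_multiplier * bs.std(ddof=1)),
        n_reference=int(min(heights.size, bs.size)),
        reference_group=reference_group,
        sd_multiplier=sd_multiplier,
    )


def classify_micrographia(
    profile: MicrographiaProfile, thresholds: ReferenceThresholds
) -> MicrographiaProfile:
    """Fill the consistent/progressive flags by the strict −2 SD criterion.

    A metric strictly *below* its threshold is positive; boundary equality is
    negative.  Flags stay ``None`` when the underlying metric is missing.
    Both flags may in principle be true for the same subject — the criteria are
    not structurally exclusive.
    """
    if not math.isnan(profile.mean_letter_height):
        profile.consistent_flag = bool(
            profile.mean_letter_height < thresholds.consistent_threshold
        )
    else:
        profile.consistent_flag = None
    if not math.isnan(profile.progressive_b):
        profile.progressive_flag = bool(
            profile.progressive_b < thresholds.progressive_threshold
        )
    else:
        profile.progressive_flag = None
    return profile


# -- table-level interface ---------------------------------------------------

_SAMPLE_COLUMNS = {
    "height_T": "letter_T_mm",
    "height_p": "letter_p_mm",
    "height_a_umlautless": "letter_a_mm",
    "sample_width": "width_mm",
    "house_width": "house_w_cm",
    "house_height": "house_h_cm",
}
_A_COLUMNS = [f"a{i}_mm" for i in range(1, 7)]


def sample_from_row(row: pd.Series) -> WritingSample:
    """Build a :class:`WritingSample` from one cohort-table row."""
    kwargs = {
        attr: (float(row[col]) if col in row and pd.notna(row[col]) else None)
        for attr, col in _SAMPLE_COLUMNS.items()
    }
    if all(c in row for c in _A_COLUMNS):
        a = [row[c] for c in _A_COLUMNS]
        kwargs["a_heights"] = None if any(pd.isna(v) for v in a) else [float(v) for v in a]
    return WritingSample(**kwargs)


def _column_matrix(cohort: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    out = np.full((len(cohort), len(cols)), np.nan)
    for j, c in enumerate(cols):
        if c in cohort.columns:
            out[:, j] = pd.to_numeric(cohort[c], errors="coerce").to_numpy(dtype=float)
    return out


def compute_metrics_table(
    cohort: pd.DataFrame, thresholds: Optional[ReferenceThresholds] = None
) -> pd.DataFrame:
    """Per-subject micrographia metrics for a cohort table (vectorized).

    Equivalent to :func:`compute_profile` row by row.  When ``thresholds`` is
    None they are derived from the rows with ``group == "HC"``; pass explicit
    thresholds to reuse an external reference.  Returns one row per subject:
    subject_id, mean_letter_height_mm, writing_area_mm2, progressive_b,
    drawing_area_cm2, consistent_flag, progressive_flag, exclusion_reason.
    """
    letters = _column_matrix(cohort, ["letter_T_mm", "letter_p_mm", "letter_a_mm"])
    letters_ok = np.all(np.isfinite(letters) & (letters > 0), axis=1)
    mean_h = np.where(letters_ok, letters.mean(axis=1), np.nan)

    width = _column_matrix(cohort, ["width_mm"])[:, 0]
    width_ok = np.isfinite(width) & (width > 0)
    area = np.where(letters_ok & width_ok, mean_h * width, np.nan)

    a = _column_matrix(cohort, _A_COLUMNS)
    a_ok = np.all(np.isfinite(a) & (a > 0), axis=1)
    xc = A_INDEX - A_INDEX.mean()
    slope = (a - a.mean(axis=1, keepdims=True)) @ xc / np.dot(xc, xc)
    b = np.where(a_ok, slope, np.nan)

    house = _column_matrix(cohort, ["house_w_cm", "house_h_cm"])
    house_ok = np.all(np.isfinite(house) & (house > 0), axis=1)
    drawing = np.where(house_ok, house[:, 0] * house[:, 1], np.nan)

    groups = cohort["group"].to_numpy()
    if thresholds is None:
        hc = groups == "HC"
        hc_profiles = [
            MicrographiaProfile(mean_letter_height=h, progressive_b=s)
            for h, s in zip(mean_h[hc], b[hc])
        ]
        thresholds = derive_reference_thresholds(hc_profiles)

    consistent = [
        bool(h < thresholds.consistent_threshold) if math.isfinite(h) else None
        for h in mean_h
    ]
    progressive = [
        bool(s < thresholds.progressive_threshold) if math.isfinite(s) else None
        for s in b
    ]

    reasons = []
    for i in range(len(cohort)):
        r = []
        if not letters_ok[i]:
            r.append("incomplete letter heights (T, p, ä)")
        elif not width_ok[i]:
            r.append("missing or invalid sample width")
        if not a_ok[i]:
            r.append("fewer than six valid 'a' heights")
        if not house_ok[i]:
            r.append("missing house dimensions")
        reasons.append("; ".join(r))

    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "group": groups,
            "mean_letter_height_mm": mean_h,
            "writing_area_mm2": area,
            "progressive_b": b,
            "drawing_area_cm2": drawing,
            "consistent_flag": consistent,
            "progressive_flag": progressive,
            "exclusion_reason": reasons,
        }
    )
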