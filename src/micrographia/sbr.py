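"""Dopamine-transporter specific binding ratios (SBR) from VOI-level uptake.

The SBR for a striatal region is (VOI_region − VOI_occipital) / VOI_occipital,
with the occipital cortex as reference tissue — a dimensionless index of DAT
availability.  Six regions are quantified (left/right caudate, anterior
putamen, posterior putamen) and aggregated bilaterally by averaging the two
sides' SBRs (the FP-CIT reporting convention; ratios are averaged, never the
raw uptakes).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = ["RegionalUptake", "SBRPanel", "compute_sbr", "compute_sbr_panel", "compute_sbr_table"]

#: (attribute on RegionalUptake, cohort-table column) for the six target VOIs
REGION_COLUMNS = [
    ("caudate_left", "voi_caud_l"),
    ("caudate_right", "voi_caud_r"),
    ("ant_putamen_left", "voi_antput_l"),
    ("ant_putamen_right", "voi_antput_r"),
    ("post_putamen_left", "voi_postput_l"),
    ("post_putamen_right", "voi_postput_r"),
]
OCCIPITAL_COLUMN = "voi_occ"


@dataclass(frozen=True)
class RegionalUptake:
    """Mean VOI uptakes (arbitrary units) for one subject."""

    caudate_left: float
    caudate_right: float
    ant_putamen_left: float
    ant_putamen_right: float
    post_putamen_left: float
    post_putamen_right: float
    occipital: float


@dataclass(frozen=True)
class SBRPanel:
    """Regional SBRs plus bilateral means for one subject."""

    caudate_left: float
    caudate_right: float
    ant_putamen_left: float
    ant_putamen_right: float
    post_putamen_left: float
    post_putamen_right: float
    caudate_mean: float
    ant_putamen_mean: float
    post_putamen_mean: float


def compute_sbr(region_uptake: float, occipital_uptake: float) -> float:
    """SBR = (region − occipital) / occipital; requires occipital > 0."""
    if not occipital_uptake > 0:
        raise ValueError(
            f"occipital reference uptake must be positive, got {occipital_uptake}"
        )
    return (region_uptake - occipital_uptake) / occipital_uptake


def compute_sbr_panel(uptake: RegionalUptake) -> SBRPanel:
    """All six regional SBRs and the three bilateral means for one subject."""
    for f in fields(uptake):
        v = getattr(uptake, f.name)
        if v is None or not v == v:  # None or NaN
            raise ValueError(f"missing uptake field: {f.name}")
    occ = uptake.occipital
    sbr = {attr: compute_sbr(getattr(uptake, attr), occ) for attr, _ in REGION_COLUMNS}
    return SBRPanel(
        **sbr,
        caudate_mean=(sbr["caudate_left"] + sbr["caudate_right"]) / 2.0,
        ant_putamen_mean=(sbr["ant_putamen_left"] + sbr["ant_putamen_right"]) / 2.0,
        post_putamen_mean=(sbr["post_putamen_left"] + sbr["post_putamen_right"]) / 2.0,
    )


def compute_sbr_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized SBR panel over the VOI columns of a cohort table.

    Emits one row per subject with columns sbr_caudate_l/r, sbr_antput_l/r,
    sbr_postput_l/r and the three bilateral means.  Rows with any missing VOI
    value get NaN SBRs (the subject was not scanned or quantification failed).
    """
    occ = cohort[OCCIPITAL_COLUMN].astype(float)
    if (occ <= 0).any():
        bad = cohort.loc[occ <= 0, "subject_id"].tolist()
        raise ValueError(f"non-positive occipital reference uptake for subjects {bad}")
    out = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})
    short = {
        "voi_caud_l": "sbr_caudate_l",
        "voi_caud_r": "sbr_caudate_r",
        "voi_antput_l": "sbr_antput_l",
        "voi_antput_r": "sbr_antput_r",
        "voi_postput_l": "sbr_postput_l",
        "voi_postput_r": "sbr_postput_r",
    }
    for voi_col, sbr_col in short.items():
        out[sbr_col] = (cohort[voi_col].astype(float) - occ.to_numpy()) / occ.to_numpy()
    out["sbr_caudate_mean"] = (out["sbr_caudate_l"] + out["sbr_caudate_r"]) / 2.0
    out["sbr_antput_mean"] = (out["sbr_antput_l"] + out["sbr_antput_r"]) / 2.0
    out["sbr_postput_mean"] = (out["sbr_postput_l"] + out["sbr_postput_r"]) / 2.0
    return out
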