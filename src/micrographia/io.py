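"""Cohort table schema, validated readers/writers and JSON serialization.

The cohort file is a CSV or TSV with one row per subject.  Mandatory columns
are the subject id, the group label (PD / ET / HC) and MMSE; all measurement
columns are optional per subject (missing token "NA") and unknown extra
columns are preserved untouched.  Subjects with MMSE below 18 are excluded at
load time with a logged count, matching the study's inclusion rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortLoadResult", "read_cohort", "write_cohort", "dump_json", "COLUMN_TYPES"]

log = logging.getLogger("micrographia")

MISSING_TOKEN = "NA"
GROUPS = ("PD", "ET", "HC")
MMSE_MINIMUM = 18

#: typed schema of the cohort table (column -> kind)
COLUMN_TYPES: dict[str, str] = {
    "subject_id": "str",
    "group": "category",
    "age": "float",
    "sex": "category",
    "handedness": "category",
    "levodopa": "category",
    "ledd": "float",
    "updrs3": "float",
    "brady": "float",
    "duration_months": "float",
    "mmse": "float",
    "bdi": "float",
    "predominant_side": "category",
    "letter_T_mm": "float",
    "letter_p_mm": "float",
    "letter_a_mm": "float",
    "a1_mm": "float", "a2_mm": "float", "a3_mm": "float",
    "a4_mm": "float", "a5_mm": "float", "a6_mm": "float",
    "width_mm": "float",
    "house_w_cm": "float",
    "house_h_cm": "float",
    "voi_caud_l": "float", "voi_caud_r": "float",
    "voi_antput_l": "float", "voi_antput_r": "float",
    "voi_postput_l": "float", "voi_postput_r": "float",
    "voi_occ": "float",
}
MANDATORY = ("subject_id", "group", "mmse")


@dataclass
class CohortLoadResult:
    cohort: pd.DataFrame
    n_loaded: int
    n_excluded_mmse: int
    n_excluded_malformed: int
    exclusions: list[str] = field(default_factory=list)


def read_cohort(path, sep: str | None = None, strict: bool = True) -> CohortLoadResult:
    """Load and validate a cohort CSV/TSV.

    Delimiter is auto-detected from the header line unless ``sep`` is given.
    With ``strict`` (default) a missing mandatory column or duplicate
    subject_id raises; malformed numeric cells become missing with a logged
    count when ``strict`` is off, and raise otherwise.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN], keep_default_na=True)
    missing_cols = [c for c in MANDATORY if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks mandatory columns: {missing_cols}")

    n_malformed = 0
    for col, kind in COLUMN_TYPES.items():
        if col not in df.columns or kind not in ("float",):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            if strict:
                raise ValueError(
                    f"non-numeric values in column {col!r}: "
                    f"{df.loc[bad, col].head().tolist()}"
                )
            n_malformed += int(bad.sum())
        df[col] = coerced

    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes[:5]}")
    if df["group"].isna().any():
        raise ValueError("group label missing for some subjects")
    unknown_groups = set(df["group"].unique()) - set(GROUPS)
    if unknown_groups:
        raise ValueError(f"unknown group labels {sorted(unknown_groups)}; expected {GROUPS}")

    low_mmse = df["mmse"].notna() & (df["mmse"] < MMSE_MINIMUM)
    exclusions = [
        f"subject {sid}: MMSE {v:.0f} < {MMSE_MINIMUM}"
        for sid, v in zip(df.loc[low_mmse, "subject_id"], df.loc[low_mmse, "mmse"])
    ]
    n_mmse = int(low_mmse.sum())
    if n_mmse:
        log.info("excluding %d subjects with MMSE < %d", n_mmse, MMSE_MINIMUM)
    df = df.loc[~low_mmse].reset_index(drop=True)
    return CohortLoadResult(
        cohort=df,
        n_loaded=len(df),
        n_excluded_mmse=n_mmse,
        n_excluded_malformed=n_malformed,
        exclusions=exclusions,
    )


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort table with the canonical missing token."""
    cohort.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj, sig: int = 6):
    """Round floats to ``sig`` significant digits for stable, readable output."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if not np.isfinite(x):
            return None
        return float(f"{x:.{sig}g}")
    return obj


def dump_json(bundle: dict, path=None, sig: int = 6) -> str:
    """Serialize a results bundle deterministically (sorted keys, 6 sig digits)."""
    text = json.dumps(_round_floats(bundle, sig), indent=2, sort_keys=True,
                      default=_json_default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
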