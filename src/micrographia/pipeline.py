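"""End-to-end analysis pipeline on a conforming cohort table.

Reproduces the study's analysis sequence: micrographia metrics → HC reference
thresholds and classification → SBR panel → per-metric three-group comparison
(Kruskal–Wallis with Dunn–Bonferroni pairwise tests) → relative median
differences → correlation battery (micrographia vs SBR in every group;
micrographia and SBR vs motor severity in PD) → ANCOVA contrasts of PD with
versus without micrographia → ROC / Youden diagnostics for PD vs ET on all
subjects and on the early-disease subgroup.  Each stage logs the n used and
exclusions; independent stages continue when one fails.
"""

from __future__ import annotations

import logging
import time
from typing import Optional

import numpy as np
import pandas as pd

from . import diagnostics, sbr, stats, writing

log = logging.getLogger("micrographia")

#: metric column -> ROC orientation (PD writes smaller / more negative)
ROC_METRICS = {
    "mean_letter_height_mm": "lower",
    "writing_area_mm2": "lower",
    "progressive_b": "lower",
}

#: continuous variables compared across the three groups, summary-table style
COMPARISON_METRICS = [
    "mean_letter_height_mm",
    "writing_area_mm2",
    "progressive_b",
    "drawing_area_cm2",
    "sbr_caudate_mean",
    "sbr_antput_mean",
    "sbr_postput_mean",
    "sbr_postput_l",
    "sbr_postput_r",
]

RELATIVE_DIFF_PAIRS = [
    ("mean_letter_height_mm", "PD", "ET"),
    ("mean_letter_height_mm", "PD", "HC"),
    ("writing_area_mm2", "PD", "ET"),
    ("writing_area_mm2", "PD", "HC"),
    ("progressive_b", "PD", "ET"),
    ("sbr_postput_mean", "PD", "ET"),
    ("sbr_postput_mean", "PD", "HC"),
]


def _comparison_to_dict(res: stats.ComparisonResult, groups) -> dict:
    medians = {
        g: float(np.nanmedian(v)) if len(v) else None for g, v in groups.items()
    }
    iqrs = {
        g: float(np.nanpercentile(v, 75) - np.nanpercentile(v, 25)) if len(v) else None
        for g, v in groups.items()
    }
    return {
        "H": res.statistic,
        "p": res.p_value,
        "n_per_group": res.n_per_group,
        "median": medians,
        "iqr": iqrs,
        "pairwise": {
            f"{t.pair[0]}_vs_{t.pair[1]}": {
                "z": t.z, "p_raw": t.p_raw, "p_adjusted": t.p_adjusted
            }
            for t in res.pairwise
        },
    }


def run_pipeline(cohort: pd.DataFrame, config: Optional[dict] = None) -> dict:
    """Run every analysis stage and return a JSON-serializable results bundle."""
    config = config or {}
    bundle: dict = {"stages": {}, "log": []}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                status = "ok"
            except Exception as exc:  # independent stages continue
                status = f"failed: {exc}"
                log.warning("stage %s failed: %s", name, exc)
            # wall time goes to the logger only, keeping the bundle
            # byte-identical across reruns on the same inputs
            log.info("stage=%s status=%s seconds=%.3f", name, status,
                     time.perf_counter() - t0)
            bundle["log"].append({"stage": name, "status": status})
        return wrap

    joined = cohort.copy()

    @stage("micrographia_metrics")
    def _metrics():
        nonlocal joined
        hc_rows = cohort[cohort["group"] == "HC"]
        if len(hc_rows) >= 2:
            metrics = writing.compute_metrics_table(cohort)
            thr = writing.derive_reference_thresholds(
                [writing.compute_profile(writing.sample_from_row(r))
                 for _, r in hc_rows.iterrows()]
            )
            bundle["stages"]["thresholds"] = {
                "consistent_threshold_mm": thr.consistent_threshold,
                "progressive_threshold": thr.progressive_threshold,
                "n_reference": thr.n_reference,
            }
        else:
            # no usable HC reference: metrics without classification flags
            profiles = [writing.compute_profile(writing.sample_from_row(r))
                        for _, r in cohort.iterrows()]
            metrics = pd.DataFrame({
                "subject_id": cohort["subject_id"].to_numpy(),
                "group": cohort["group"].to_numpy(),
                "mean_letter_height_mm": [p.mean_letter_height for p in profiles],
                "writing_area_mm2": [p.writing_area for p in profiles],
                "progressive_b": [p.progressive_b for p in profiles],
                "drawing_area_cm2": [p.drawing_area for p in profiles],
                "consistent_flag": [None] * len(profiles),
                "progressive_flag": [None] * len(profiles),
                "exclusion_reason": ["; ".join(p.exclusion_reasons) for p in profiles],
            })
            bundle["stages"]["thresholds"] = {
                "error": "HC reference unavailable (fewer than 2 HC subjects)"
            }
        joined = joined.merge(metrics.drop(columns=["group"]), on="subject_id")
        counts = metrics[metrics["group"] == "PD"]
        bundle["stages"]["classification"] = {
            "n_consistent_pd": int(counts["consistent_flag"].eq(True).sum()),
            "n_progressive_pd": int(counts["progressive_flag"].eq(True).sum()),
            "n_excluded_samples": int((metrics["exclusion_reason"] != "").sum()),
        }

    @stage("sbr_panel")
    def _sbr():
        nonlocal joined
        panel = sbr.compute_sbr_table(cohort)
        joined = joined.merge(panel, on="subject_id")
        bundle["stages"]["sbr"] = {
            "n": int(panel["sbr_postput_mean"].notna().sum()),
            "median_postput_mean_by_group": {
                g: float(sub["sbr_postput_mean"].median())
                for g, sub in panel.merge(
                    cohort[["subject_id", "group"]], on="subject_id"
                ).groupby("group")
            },
        }

    @stage("group_comparisons")
    def _compare():
        section = {}
        for col in COMPARISON_METRICS:
            if col not in joined.columns:
                continue
            gm = stats.GroupedMetric.from_frame(joined, col)
            if len(gm.groups) < 2:
                continue
            res = stats.compare_groups(gm)
            section[col] = _comparison_to_dict(res, gm.groups)
        bundle["stages"]["group_comparisons"] = section

    @stage("relative_differences")
    def _reldiff():
        section = {}
        for col, a, b in RELATIVE_DIFF_PAIRS:
            if col not in joined.columns:
                continue
            gm = stats.GroupedMetric.from_frame(joined, col)
            if a in gm.groups and b in gm.groups:
                section[f"{col}_{a}_vs_{b}_pct"] = round(
                    stats.relative_median_difference(gm, a, b), 1
                )
        bundle["stages"]["relative_differences"] = section

    @stage("correlations")
    def _correlate():
        section = {}
        sbr_cols = ["sbr_caudate_mean", "sbr_antput_mean", "sbr_postput_mean"]
        micro_cols = ["mean_letter_height_mm", "progressive_b", "drawing_area_cm2"]
        for g, sub in joined.groupby("group"):
            block = {}
            for m in micro_cols:
                for s in sbr_cols:
                    if m in sub.columns and s in sub.columns:
                        rho, p = stats.spearman_rho(sub[m], sub[s])
                        block[f"{m}__{s}"] = {"rho": rho, "p": p}
            section[str(g)] = block
        pd_rows = joined[joined["group"] == "PD"]
        clin = {}
        for m in ["mean_letter_height_mm", "progressive_b", *sbr_cols]:
            for c in ["updrs3", "brady"]:
                if m in pd_rows.columns and c in pd_rows.columns:
                    rho, p = stats.spearman_rho(pd_rows[m], pd_rows[c])
                    clin[f"{m}__{c}"] = {"rho": rho, "p": p}
        section["PD_clinical"] = clin
        bundle["stages"]["correlations"] = section

    @stage("ancova")
    def _ancova():
        section = {}
        pd_rows = joined[joined["group"] == "PD"]
        covs = pd.DataFrame({
            "age": pd_rows["age"],
            "sex": (pd_rows["sex"] == "M").astype(float),
            "mmse": pd_rows["mmse"],
            "updrs3": pd_rows["updrs3"],
        })
        for flag in ("consistent_flag", "progressive_flag"):
            grp = pd_rows[flag].eq(True)
            if grp.nunique() < 2:
                section[flag] = {"error": "only one micrographia class present"}
                continue
            res = stats.ancova_group_contrast(
                pd_rows["sbr_postput_mean"], grp.astype(int), covs,
            )
            section[flag] = {
                "adjusted_difference": res.adjusted_difference,
                "t": res.t_statistic, "p": res.p_value,
                "n_used": res.n_used, "n_dropped": res.n_dropped,
            }
        bundle["stages"]["ancova_sbr_by_micrographia"] = section

    @stage("roc")
    def _roc():
        section = {}
        pd_et = joined[joined["group"].isin(["PD", "ET"])]
        subsets = {"all": pd_et}
        try:
            subsets["early_disease"] = diagnostics.apply_subgroup(pd_et)
        except ValueError as exc:
            section["early_disease"] = {"error": str(exc)}
        for label, sub in subsets.items():
            block = {}
            for col, orientation in ROC_METRICS.items():
                if col not in sub.columns:
                    continue
                ok = sub[col].notna()
                try:
                    res = diagnostics.evaluate_metric(
                        sub.loc[ok, col].to_numpy(),
                        sub.loc[ok, "group"].to_numpy(),
                        metric_name=col,
                        orientation=orientation,
                        subgroup_label=label,
                    )
                    block[col] = res.to_dict()
                except ValueError as exc:
                    block[col] = {"error": str(exc)}
            section[label] = block
        bundle["stages"]["roc"] = section

    bundle["n_subjects"] = int(len(cohort))
    bundle["n_per_group"] = {
        str(g): int(n) for g, n in cohort["group"].value_counts().items()
    }
    return bundle
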