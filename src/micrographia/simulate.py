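"""Synthetic PD / ET / HC cohort generator.

No subject-level data accompany the published cohort, so the pipeline is
exercised on synthetic cohorts built to match its printed summary statistics:
per-group medians and IQRs of the writing metrics, regional SBRs and clinical
scores, the published categorical rates, and the reported Spearman
rank-correlation structure (letter height vs MDS-UPDRS III ≈ −0.21 in PD,
posterior-putamen SBR vs MDS-UPDRS III in the −0.28..−0.43 range, micrographia
vs SBR ≈ 0).

Marginals are fitted analytically from (median, IQR): log-normal for positive
skewed measures (μ = ln median, σ = asinh(IQR / 2·median) / z₀.₇₅) and normal
for signed ones (mean = median, σ = IQR / 1.349).  Dependence is imposed with
a Gaussian copula; target Spearman correlations ρ are converted to latent
Pearson correlations via r = 2·sin(πρ/6).

Subject-level raw fields are decomposed consistently so the measurement
functions recover the latent values exactly: the three letter heights average
to the latent mean height (zero-sum deviations), the sample width is
area / mean height, the six "a" heights carry the latent b value plus
slope-free noise, the house sides multiply to the drawing area, and VOI
uptakes are occipital × (1 + SBR) with a fixed occipital reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as ss
import yaml

from .writing import A_INDEX, compute_metrics_table, derive_reference_thresholds

__all__ = [
    "Marginal",
    "CohortConfig",
    "fit_marginal",
    "load_default_config",
    "load_config",
    "generate_cohort",
    "inject_micrographia_cases",
]

_Z75 = ss.norm.ppf(0.75)  # 0.6744897501960817

#: order of the copula-correlated variables in every rank_correlations matrix
COPULA_VARIABLES = ["letter_height", "progressive_b", "updrs3", "brady", "sbr_postput"]


@dataclass(frozen=True)
class Marginal:
    """A univariate marginal parameterized to hit a target median and IQR."""

    family: str               # "normal" | "lognormal" | "constant"
    median: float
    iqr: float
    integer: bool = False
    clip: Optional[tuple[float, float]] = None

    @property
    def sigma(self) -> float:
        if self.family == "normal":
            return self.iqr / (2.0 * _Z75)
        if self.family == "lognormal":
            # IQR = 2 e^mu sinh(sigma z75)  =>  sigma = asinh(IQR / 2 median)/z75
            return math.asinh(self.iqr / (2.0 * self.median)) / _Z75
        return 0.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.family == "constant":
            x = np.full_like(u, self.median)
        elif self.family == "normal":
            x = ss.norm.ppf(u, loc=self.median, scale=self.sigma)
        elif self.family == "lognormal":
            x = ss.lognorm.ppf(u, s=self.sigma, scale=self.median)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return x

    def finalize(self, x: np.ndarray) -> np.ndarray:
        """Apply instrument rounding (half-up) and range clipping."""
        if self.integer:
            x = np.floor(x + 0.5)
        if self.clip is not None:
            x = np.clip(x, self.clip[0], self.clip[1])
        return x


def fit_marginal(median: float, iqr: float, family: str, **kw) -> Marginal:
    """Distribution matching the target median and IQR analytically.

    ``iqr == 0`` degenerates to a point mass at the median (e.g. a single
    treated subject defining the LEDD column of a group).
    """
    if iqr < 0:
        raise ValueError("IQR must be non-negative")
    if iqr == 0:
        family = "constant"
    if family == "lognormal" and median <= 0:
        raise ValueError("lognormal family requires a positive median")
    if family not in ("normal", "lognormal", "constant"):
        raise ValueError(f"unknown family {family!r}")
    return Marginal(family=family, median=float(median), iqr=float(iqr), **kw)


@dataclass
class GroupConfig:
    continuous: dict[str, Marginal]
    categorical: dict[str, dict[str, float]]     # variable -> {level: probability}
    rank_correlations: np.ndarray                # Spearman targets, COPULA_VARIABLES order


@dataclass
class CohortConfig:
    group_sizes: dict[str, int]
    groups: dict[str, GroupConfig]
    seed: int = 42
    occipital_uptake: float = 10.0
    postput_side_latent_correlation: float = 0.95
    striatal_latent_correlation: float = 0.80
    letter_height_noise_sd_mm: float = 0.30
    a_height_noise_sd_mm: float = 0.30
    side_asymmetry_sd: float = 0.05
    house_aspect_log_sd: float = 0.20
    missing_rate: float = 0.0
    extra: dict = dc_field(default_factory=dict)


def _parse_group(raw: dict) -> GroupConfig:
    continuous = {}
    for name, spec in raw.get("continuous", {}).items():
        spec = dict(spec)
        clip = spec.pop("clip", None)
        continuous[name] = fit_marginal(
            spec.pop("median"),
            spec.pop("iqr"),
            spec.pop("family"),
            integer=bool(spec.pop("integer", False)),
            clip=tuple(clip) if clip is not None else None,
        )
    categorical = {}
    for name, counts in raw.get("categorical", {}).items():
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError(f"categorical variable {name!r} has no counts")
        categorical[name] = {str(k): v / total for k, v in counts.items()}
    corr = np.asarray(raw["rank_correlations"], dtype=float)
    if corr.shape != (len(COPULA_VARIABLES),) * 2:
        raise ValueError(
            f"rank_correlations must be {len(COPULA_VARIABLES)}×{len(COPULA_VARIABLES)} "
            f"in the order {COPULA_VARIABLES}"
        )
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("rank_correlations must be symmetric with unit diagonal")
    return GroupConfig(continuous=continuous, categorical=categorical, rank_correlations=corr)


def _parse_config(raw: dict) -> CohortConfig:
    known = {
        "seed", "occipital_uptake", "postput_side_latent_correlation",
        "striatal_latent_correlation", "letter_height_noise_sd_mm",
        "a_height_noise_sd_mm", "side_asymmetry_sd", "house_aspect_log_sd",
        "missing_rate",
    }
    kwargs = {k: raw[k] for k in known if k in raw}
    extra = {k: v for k, v in raw.items() if k not in known | {"group_sizes", "groups", "copula_variables"}}
    return CohortConfig(
        group_sizes={str(k): int(v) for k, v in raw["group_sizes"].items()},
        groups={str(k): _parse_group(v) for k, v in raw["groups"].items()},
        extra=extra,
        **kwargs,
    )


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return _parse_config(yaml.safe_load(fh))


def load_default_config() -> CohortConfig:
    """The packaged configuration calibrated to the published cohort summaries."""
    text = resources.files("micrographia").joinpath("data/table1_defaults.yaml").read_text()
    return _parse_config(yaml.safe_load(text))


def _latent_pearson(spearman: np.ndarray) -> np.ndarray:
    """Convert a Spearman target matrix to the latent Gaussian correlation."""
    r = 2.0 * np.sin(np.pi * spearman / 6.0)
    np.fill_diagonal(r, 1.0)
    eig = np.linalg.eigvalsh(r)
    if eig.min() < -1e-10:
        raise ValueError(
            "rank-correlation matrix is not positive semidefinite after the "
            f"copula transform (min eigenvalue {eig.min():.3g}); project it to "
            "the nearest PSD matrix (clip negative eigenvalues and renormalize "
            "the diagonal) before use"
        )
    return r


def _copula_draw(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    """n draws of correlated standard-normal latents (columns = variables)."""
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return rng.standard_normal((n, corr.shape[0])) @ root.T


def _zero_sum_noise(rng, n: int, k: int, sd: float) -> np.ndarray:
    d = rng.normal(0.0, sd, (n, k))
    return d - d.mean(axis=1, keepdims=True)


def _generate_group(
    label: str, n: int, g: GroupConfig, cfg: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    corr = _latent_pearson(g.rank_correlations)
    z = _copula_draw(rng, corr, n)
    u = ss.norm.cdf(z)
    cont = g.continuous

    def draw(name: str, n_draw: int = None) -> np.ndarray:
        m = cont[name]
        return m.finalize(m.ppf(rng.uniform(size=n if n_draw is None else n_draw)))

    out = {"group": np.full(n, label, dtype=object)}

    # copula-linked variables
    mean_height = cont["letter_height"].ppf(u[:, 0])
    b = cont["progressive_b"].ppf(u[:, 1])
    out["updrs3"] = cont["updrs3"].finalize(cont["updrs3"].ppf(u[:, 2]))
    out["brady"] = cont["brady"].finalize(cont["brady"].ppf(u[:, 3]))
    z_pp = z[:, 4]

    # posterior putamen: each side has its own marginal, sharing a latent factor
    w_side = cfg.postput_side_latent_correlation
    e = rng.standard_normal((n, 2))
    z_l = math.sqrt(w_side) * z_pp + math.sqrt(1.0 - w_side) * e[:, 0]
    z_r = math.sqrt(w_side) * z_pp + math.sqrt(1.0 - w_side) * e[:, 1]
    sbr_pp_l = cont["sbr_postput_l"].ppf(ss.norm.cdf(z_l))
    sbr_pp_r = cont["sbr_postput_r"].ppf(ss.norm.cdf(z_r))

    # caudate / anterior putamen: bilateral-mean marginal, symmetric side split
    rho = cfg.striatal_latent_correlation
    sides = {}
    for region in ("sbr_caudate", "sbr_antput"):
        z_reg = rho * z_pp + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        mean_sbr = cont[region].ppf(ss.norm.cdf(z_reg))
        delta = np.clip(rng.normal(0.0, cfg.side_asymmetry_sd, n), -0.5, 0.5)
        sides[region] = (mean_sbr * (1.0 + delta), mean_sbr * (1.0 - delta))
    occ = cfg.occipital_uptake
    out["voi_caud_l"], out["voi_caud_r"] = (occ * (1 + s) for s in sides["sbr_caudate"])
    out["voi_antput_l"], out["voi_antput_r"] = (occ * (1 + s) for s in sides["sbr_antput"])
    out["voi_postput_l"] = occ * (1.0 + sbr_pp_l)
    out["voi_postput_r"] = occ * (1.0 + sbr_pp_r)
    out["voi_occ"] = np.full(n, occ)

    # writing sample: three letters averaging exactly to the latent mean height
    dev = _zero_sum_noise(rng, n, 3, cfg.letter_height_noise_sd_mm)
    with np.errstate(divide="ignore"):
        shrink = np.minimum(1.0, 0.8 * mean_height / np.abs(dev).max(axis=1))
    letters = mean_height[:, None] + dev * shrink[:, None]
    out["letter_T_mm"], out["letter_p_mm"], out["letter_a_mm"] = letters.T

    area = draw("writing_area")
    out["width_mm"] = area / mean_height

    # six "a" heights: latent slope b exactly, noise projected slope-free
    xc = A_INDEX - A_INDEX.mean()
    noise = rng.normal(0.0, cfg.a_height_noise_sd_mm, (n, 6))
    noise -= np.outer(noise @ xc / np.dot(xc, xc), xc)
    base = np.maximum(mean_height, 0.1 + 2.5 * np.abs(b) + np.abs(noise).max(axis=1))
    a_heights = base[:, None] + np.outer(b, xc) + noise
    for i in range(6):
        out[f"a{i+1}_mm"] = a_heights[:, i]

    d_area = draw("drawing_area")
    aspect = np.exp(rng.normal(0.0, cfg.house_aspect_log_sd, n))
    out["house_w_cm"] = np.sqrt(d_area * aspect)
    out["house_h_cm"] = np.sqrt(d_area / aspect)

    # independent clinical variables
    out["age"] = draw("age")
    out["mmse"] = draw("mmse")
    out["bdi"] = draw("bdi")
    out["duration_months"] = (
        draw("duration_months") if "duration_months" in cont else np.full(n, np.nan)
    )

    # categorical variables
    for var in ("sex", "handedness", "levodopa", "predominant_side"):
        if var in g.categorical:
            levels = list(g.categorical[var])
            p = np.array([g.categorical[var][lv] for lv in levels])
            out[var] = rng.choice(levels, size=n, p=p / p.sum())
        else:
            out[var] = np.full(n, "NA" if var == "predominant_side" else "no", dtype=object)

    # LEDD only for levodopa-treated subjects
    ledd = np.full(n, np.nan)
    if "ledd" in cont:
        treated = np.asarray(out["levodopa"]) == "yes"
        ledd[treated] = draw("ledd", int(treated.sum()))
    out["ledd"] = ledd

    if cfg.missing_rate > 0.0:
        for col in ("letter_T_mm", "letter_p_mm", "letter_a_mm", "width_mm",
                    "house_w_cm", "house_h_cm"):
            drop = rng.uniform(size=n) < cfg.missing_rate
            out[col] = np.where(drop, np.nan, out[col])

    return pd.DataFrame(out)


def generate_cohort(config: Optional[CohortConfig] = None, seed: Optional[int] = None) -> pd.DataFrame:
    """Deterministic synthetic cohort table for a configuration.

    ``seed`` overrides ``config.seed``.  Column schema matches the cohort CSV
    consumed by every other module; subject ids are S0001, S0002, …
    """
    cfg = config or load_default_config()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = [
        _generate_group(label, cfg.group_sizes[label], cfg.groups[label], cfg, rng)
        for label in cfg.group_sizes
    ]
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "subject_id", [f"S{i+1:05d}" for i in range(len(cohort))])
    ordered = [
        "subject_id", "group", "age", "sex", "handedness", "levodopa", "ledd",
        "updrs3", "brady", "duration_months", "mmse", "bdi", "predominant_side",
        "letter_T_mm", "letter_p_mm", "letter_a_mm",
        "a1_mm", "a2_mm", "a3_mm", "a4_mm", "a5_mm", "a6_mm", "width_mm",
        "house_w_cm", "house_h_cm",
        "voi_caud_l", "voi_caud_r", "voi_antput_l", "voi_antput_r",
        "voi_postput_l", "voi_postput_r", "voi_occ",
    ]
    return cohort[ordered]


def inject_micrographia_cases(
    cohort: pd.DataFrame, n_consistent: int, n_progressive: int
) -> pd.DataFrame:
    """Rewrite writing fields of selected PD subjects to force known case counts.

    Chooses PD subjects that are currently negative on both −2 SD criteria
    (thresholds from the cohort's own HC group) and pushes ``n_consistent`` of
    them below the letter-height threshold (with a flat "a" sequence, so they
    do not become progressive) and ``n_progressive`` others below the b-value
    threshold (letter heights untouched).  The two injected sets are disjoint
    and only writing columns change; naturally occurring cases are left alone,
    so the cohort ends with *at least* the requested counts flagged.
    """
    if n_consistent < 0 or n_progressive < 0:
        raise ValueError("case counts must be non-negative")
    metrics = compute_metrics_table(cohort)
    hc_profiles = metrics[metrics["group"] == "HC"]
    thr = derive_reference_thresholds(
        [p for p in _profiles_from_metrics(hc_profiles)]
    )
    if thr.consistent_threshold <= 0:
        raise ValueError("HC-derived height threshold is non-positive; injection infeasible")
    negative_both = (
        (metrics["group"] == "PD")
        & ~metrics["consistent_flag"].fillna(True).astype(bool)
        & ~metrics["progressive_flag"].fillna(True).astype(bool)
    )
    eligible = metrics.index[negative_both]
    if len(eligible) < n_consistent + n_progressive:
        raise ValueError(
            f"only {len(eligible)} PD subjects are negative on both criteria; "
            f"cannot inject {n_consistent}+{n_progressive} cases"
        )
    out = cohort.copy()
    # metrics rows are positional (0..n-1 in cohort order); address by position
    cons_pos = list(eligible[:n_consistent])
    prog_pos = list(eligible[n_consistent: n_consistent + n_progressive])

    small = 0.8 * thr.consistent_threshold
    for col in ("letter_T_mm", "letter_p_mm", "letter_a_mm"):
        out.iloc[cons_pos, out.columns.get_loc(col)] = small
    for i in range(1, 7):  # flat sequence: slope 0, above any negative b threshold
        out.iloc[cons_pos, out.columns.get_loc(f"a{i}_mm")] = small

    b_new = thr.progressive_threshold - 0.5 * abs(thr.progressive_threshold) - 0.05
    base = max(5.0, 0.2 + 2.5 * abs(b_new))
    xc = A_INDEX - A_INDEX.mean()
    for i in range(1, 7):
        out.iloc[prog_pos, out.columns.get_loc(f"a{i}_mm")] = base + b_new * xc[i - 1]
    return out


def _profiles_from_metrics(metrics: pd.DataFrame):
    from .writing import MicrographiaProfile

    for _, row in metrics.iterrows():
        yield MicrographiaProfile(
            mean_letter_height=row["mean_letter_height_mm"],
            writing_area=row["writing_area_mm2"],
            progressive_b=row["progressive_b"],
            drawing_area=row["drawing_area_cm2"],
        )
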