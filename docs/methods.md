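# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-cohort generator does and does not emulate, and
the places where the design was genuinely open.

## Writing-sample metrics

The writing task is the fixed Finnish sentence *"Tänään on kaunis päivä"*
written under a drawn house. One designated instance each of "T", "p" and "ä"
(measured without the umlaut) supplies the **mean letter height** (mm); which
instance is measured does not affect any downstream computation, so the schema
carries a single value per letter. The **writing area** (mm²) is the mean
letter height times the width of the writing sample. The six "a"-class letters
of the sentence (the a/ä occurrences in writing order, 3+1+2 = 6) supply the
**b value**: the ordinary-least-squares slope of height against letter index
1..6 with unit spacing, computed in closed form as
Σ(x−x̄)(y−ȳ)/Σ(x−x̄)². Physical x-positions on the page are unavailable, so the
abscissa is ordinal; the slope's units are mm per letter position and it is
invariant to the index origin. The **drawing area** (cm²) is house width ×
height.

Missing or non-positive measurements make the affected metric missing with a
recorded exclusion reason; nothing is imputed. This mirrors clinical practice,
where incomplete or two-row samples are excluded.

### −2 SD classification

A subject is positive for consistent (resp. progressive) micrographia when the
mean letter height (resp. b value) is strictly below the healthy-control mean
minus two healthy-control standard deviations. The SD uses the n−1 (sample)
denominator, standard for small reference groups. Boundary equality is
negative ("below" is strict). The two criteria are not structurally exclusive:
a subject can in principle satisfy both; observed cohorts may simply contain
none.

## Specific binding ratios

SBR = (VOI_region − VOI_occipital)/VOI_occipital, occipital cortex as the
reference tissue, for left/right caudate, anterior putamen and posterior
putamen. Bilateral summaries average the two sides' *ratios*, the convention
in FP-CIT reporting — not the SBR of pooled uptakes, although the two coincide
when the occipital reference is shared within subject. Scanner calibration and
image reconstruction are upstream of this package; it consumes quantified
VOI means.

## Statistics

- **Kruskal–Wallis** with the tie correction H/(1 − Σ(t³−t)/(N³−N)) and a
  chi-square (k−1 df) p-value (delegated to scipy, which implements exactly
  this form). All-identical pooled values degenerate to H = 0, p = 1.
- **Dunn pairwise tests**: z = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − ΣT/(12(N−1)))(1/nᵢ+1/nⱼ)]
  on pooled midranks with the tie term, two-sided normal p, Bonferroni factor
  equal to the number of pairs *within each variable* (3 for three groups) —
  the correction family is per-variable pairwise comparisons, not the whole
  table of variables.
- **Spearman's ρ** via midranks with the t approximation for p.
- **Relative median difference**: 100 × (median_b − median_a)/median_b, "how
  much smaller a is than b". Medians use the conventional midpoint definition.
  On a signed scale with a negative reference median the sign flips; such
  values are reported as magnitudes.
- **ANCOVA**: OLS of the outcome on a binary group flag plus age, sex (binary
  indicator), MMSE and MDS-UPDRS III total (the operationalization of
  "cognition" and "motor symptom severity"), with listwise deletion and a
  rank check that names a collinear column. The group term's t test is
  reported. Null calibration (type-I error at α = 0.05) is verified by
  simulation in the acceptance tests.
- **Categorical tests**: Pearson chi-square without continuity correction when
  ≥ 80% of expected cell counts are ≥ 5, else Fisher's exact test for 2×2
  tables. An exact test for larger sparse tables is not available in the
  Python stack; those fall back to chi-square with the caveat recorded in the
  returned method string.
- Two-sided tests throughout, α = 0.05.

## Diagnostic accuracy

PD is the disease (sensitivity) class, ET the control (specificity) class.
Because PD medians lie below ET medians for letter height, writing area and
b value, the default orientation calls a subject positive at score ≤ cutoff;
a `higher` orientation is available. Candidate cutoffs are the observed data
values themselves (not midpoints) plus the two infinite extremes, so reported
cutoffs are attained in the data. The AUC is the Mann–Whitney probability
P(score_PD < score_ET) + ½P(tie), which the trapezoidal integral of the ROC
points reproduces exactly; both are implemented and asserted equal. The 95%
CI uses the DeLong covariance estimator by default (Hanley–McNeil available
via a flag), normal-approximated and clipped to [0, 1]. The operating point
maximizes Youden's J; ties are broken toward higher specificity (fewer false
positives), then toward the earlier threshold, making the choice
deterministic. The early-disease subgroup keeps unmedicated subjects with
symptom duration ≤ 24 months, MMSE ≥ 27 and MDS-UPDRS III ≤ 36 — every bound
inclusive; rows missing a criterion field are excluded.

Whether published operating points were exactly Youden-optimal or clinically
adjusted cannot be determined from summary statistics; Youden-optimality is
assumed.

## Interrater reliability

ICC(2,1): two-way random effects, absolute agreement, single rating
(McGraw–Wong "Case 2A" single measures), from the two-way ANOVA mean squares
of a complete subjects × raters grid, with the F-based 95% CI of the same
framework (Satterthwaite df for the rater+error combination; the construction
cross-checked against pingouin's ICC(A,1)). A grid with zero total variance
has an undefined ICC and raises rather than returning 1. Bands: below 0.50
poor, 0.50–0.75 moderate, 0.75–0.90 good, above 0.90 excellent; the quoted
phrasing leaves the boundaries ambiguous, resolved here as lower-open (0.50 →
moderate, 0.75 → moderate, 0.90 → good). Subjects with any missing rating are
dropped listwise.

## Synthetic cohort generator

The generator emulates the *summary structure* of a 146 PD / 42 ET / 38 HC
cohort: per-group medians and IQRs of the writing metrics, regional SBRs and
clinical scores; the published sex, handedness, levodopa and
predominant-side rates; and the published Spearman structure among letter
height, b value, MDS-UPDRS III, bradykinesia and posterior-putamen SBR
(height–UPDRS −0.21, SBR–UPDRS −0.35 and SBR–bradykinesia −0.37 as midpoints
of the published ranges, height–SBR 0.12, b uncorrelated; UPDRS–bradykinesia
set to 0.80 as a realistic value for a nested subscore). Correlations are
imposed by a Gaussian copula with the standard conversion r = 2 sin(πρ/6)
from target Spearman ρ to latent Pearson r; a non-PSD matrix is rejected with
a projection hint.

Marginals are fitted analytically from (median, IQR): log-normal for positive
skewed measures with μ = ln(median) and σ = asinh(IQR/(2·median))/z₀.₇₅;
normal (mean = median, σ = IQR/1.349) for signed or symmetric ones (b value,
age, MMSE, BDI). A zero IQR degenerates to a point mass (one levodopa-treated
ET subject defines that group's LEDD column). Integer instrument scores are
rounded half-up and clipped to instrument bounds (UPDRS III 0–132, MMSE
18–30 respecting the study's exclusion floor, BDI 0–63) — so their empirical
IQRs recover targets to instrument resolution, not arbitrarily finely.

Raw fields are decomposed so the measurement functions recover latent values
exactly: the three letter heights are the latent mean height plus zero-sum
deviations (SD 0.3 mm, shrunk per row to preserve positivity); the sample
width is latent area / mean height; the six "a" heights are a base plus
b × (index − 3.5) plus noise projected to have zero OLS slope, so the
computed b equals the latent b exactly; house sides multiply exactly to the
drawing area (log-normal aspect ratio, log-SD 0.2); VOI uptakes are
occipital × (1 + SBR) with the occipital reference fixed at 10 arbitrary
units (only ratios are meaningful). Posterior putamen sides have their own
marginals sharing a latent factor (inter-side correlation 0.95); caudate and
anterior putamen are generated as bilateral means (single published rows) and
split multiplicatively and symmetrically (asymmetry SD 0.05), so the
bilateral posterior-putamen mean is an emergent quantity whose median lands
near, but is not forced to, the published bilateral row — the three published
posterior-putamen rows are not jointly constrained summaries of medians.

`inject_micrographia_cases` rewrites the writing fields of PD subjects that
are negative on both −2 SD criteria so that requested numbers of consistent
and progressive cases exist, as disjoint sets: consistent injections get
uniformly small letters with a flat "a" sequence (slope 0, above any negative
b threshold); progressive injections get a steep negative slope with letter
heights untouched. Non-writing columns are preserved bit-exactly.

**What passing tests do not show about real data:** the generator draws most
variables independently given the five-variable copula block, emulates no
within-subject coupling between writing area and letter height beyond the
width construction, no bradykinesia ≤ UPDRS-total constraint, no site,
scanner or examiner effects, no longitudinal change, and no realistic
missingness unless a dropout rate is configured. Diagnostic accuracies
measured on synthetic cohorts characterize the machinery under the configured
separation, not the clinical accuracy of micrographia.

## Problem sizes and numerical tolerances

Exact identities (OLS slope vs closed form, trapezoidal vs pair-count AUC,
ICC vs ANOVA decomposition) are asserted at 1e−10–1e−12. Rank-test p-values
are compared with full permutation enumeration at pooled n ≤ 10, where the
chi-square/normal approximations deviate from exact by up to ≈ 0.03–0.05.
ANCOVA null calibration uses 2,000 simulations of n = 60. Generator marginal
recovery is checked at n = 10⁵ per group within 1% of each target, floored at
4 asymptotic standard errors of the sample quantile estimators (computed from
the fitted density): at this n the SE of a sample IQR is ~0.5% of the IQR and
the SE of the near-zero b-value median exceeds 1% of its target, so a strict
1% band would measure estimator noise rather than calibration. Copula
recovery is checked at n = 10⁴ (±0.03 on Spearman ρ, ≈ 3 SE). The full
pipeline on the default 226-subject cohort runs in well under a second.
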