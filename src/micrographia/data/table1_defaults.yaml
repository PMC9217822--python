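# Default synthetic-cohort configuration.
#
# Targets are the published group medians (IQR) for the PD / ET / HC cohort
# this package's analysis pipeline is modelled on: writing-sample metrics,
# [123I]FP-CIT SBR by region, and clinical scores, plus the reported Spearman
# rank-correlation structure among letter height, b value, MDS-UPDRS III,
# bradykinesia subscore and posterior-putamen SBR.  Categorical rates are the
# published group counts.  Marginals: lognormal for positive skewed measures,
# normal for signed / symmetric ones; integer instrument scores are rounded
# half-up and clipped to instrument bounds after sampling.
seed: 42
group_sizes:
  PD: 146
  ET: 42
  HC: 38
occipital_uptake: 10.0          # fixed reference VOI uptake (arbitrary units)
copula_variables: [letter_height, progressive_b, updrs3, brady, sbr_postput]
postput_side_latent_correlation: 0.95
striatal_latent_correlation: 0.80
letter_height_noise_sd_mm: 0.30  # zero-sum spread of T/p/a-umlautless around the mean
a_height_noise_sd_mm: 0.30       # slope-free jitter of the six sequential "a" heights
side_asymmetry_sd: 0.05          # multiplicative left/right split, caudate & ant. putamen
house_aspect_log_sd: 0.20        # log-normal aspect ratio of the drawn house
missing_rate: 0.0                # per-field writing-sample dropout (exclusion-path testing)
# published bilateral posterior-putamen medians: the generator parameterizes
# the two sides separately, so the printed bilateral summary row is kept here
# for reference comparisons
postput_bilateral_median: {PD: 0.90, ET: 2.53, HC: 2.18}

groups:
  PD:
    continuous:
      age:            {median: 66.0, iqr: 15.0, family: normal}
      updrs3:         {median: 34.0, iqr: 21.5, family: lognormal, integer: true, clip: [0, 132]}
      brady:          {median: 18.5, iqr: 13.0, family: lognormal, integer: true, clip: [0, 44]}
      mmse:           {median: 28.0, iqr: 3.0,  family: normal, integer: true, clip: [18, 30]}
      bdi:            {median: 6.0,  iqr: 7.0,  family: normal, integer: true, clip: [0, 63]}
      duration_months: {median: 18.0, iqr: 25.0, family: lognormal}
      ledd:           {median: 381.0, iqr: 158.0, family: lognormal}
      letter_height:  {median: 4.3,  iqr: 1.9,  family: lognormal}
      writing_area:   {median: 399.0, iqr: 301.0, family: lognormal}
      progressive_b:  {median: -0.14, iqr: 0.26, family: normal}
      drawing_area:   {median: 22.8, iqr: 25.4, family: lognormal}
      sbr_caudate:    {median: 2.08, iqr: 0.78, family: lognormal}
      sbr_antput:     {median: 1.56, iqr: 0.78, family: lognormal}
      sbr_postput_l:  {median: 0.89, iqr: 0.54, family: lognormal}
      sbr_postput_r:  {median: 0.93, iqr: 0.61, family: lognormal}
    categorical:
      sex: {M: 73, F: 73}
      handedness: {right: 135, left: 7, symmetrical: 4}
      levodopa: {"yes": 28, "no": 118}
      predominant_side: {right: 24, left: 36, symmetrical: 86}
    rank_correlations:
      - [ 1.00,  0.00, -0.21, -0.21,  0.12]
      - [ 0.00,  1.00,  0.00,  0.00,  0.00]
      - [-0.21,  0.00,  1.00,  0.80, -0.35]
      - [-0.21,  0.00,  0.80,  1.00, -0.37]
      - [ 0.12,  0.00, -0.35, -0.37,  1.00]
  ET:
    continuous:
      age:            {median: 66.0, iqr: 17.0, family: normal}
      updrs3:         {median: 33.5, iqr: 20.3, family: lognormal, integer: true, clip: [0, 132]}
      brady:          {median: 15.0, iqr: 11.0, family: lognormal, integer: true, clip: [0, 44]}
      mmse:           {median: 28.0, iqr: 3.0,  family: normal, integer: true, clip: [18, 30]}
      bdi:            {median: 6.8,  iqr: 9.1,  family: normal, integer: true, clip: [0, 63]}
      duration_months: {median: 27.0, iqr: 96.0, family: lognormal}
      ledd:           {median: 200.0, iqr: 0.0, family: constant}
      letter_height:  {median: 5.0,  iqr: 1.7,  family: lognormal}
      writing_area:   {median: 536.0, iqr: 397.0, family: lognormal}
      progressive_b:  {median: -0.06, iqr: 0.18, family: normal}
      drawing_area:   {median: 26.7, iqr: 22.6, family: lognormal}
      sbr_caudate:    {median: 3.09, iqr: 1.23, family: lognormal}
      sbr_antput:     {median: 2.96, iqr: 1.07, family: lognormal}
      sbr_postput_l:  {median: 2.58, iqr: 0.90, family: lognormal}
      sbr_postput_r:  {median: 2.60, iqr: 1.00, family: lognormal}
    categorical:
      sex: {M: 20, F: 22}
      handedness: {right: 36, left: 3, symmetrical: 3}
      levodopa: {"yes": 1, "no": 41}
      predominant_side: {right: 5, left: 1, symmetrical: 36}
    rank_correlations:
      - [1.00, 0.00, 0.00, 0.00, 0.00]
      - [0.00, 1.00, 0.00, 0.00, 0.00]
      - [0.00, 0.00, 1.00, 0.80, 0.00]
      - [0.00, 0.00, 0.80, 1.00, 0.00]
      - [0.00, 0.00, 0.00, 0.00, 1.00]
  HC:
    continuous:
      age:            {median: 68.0, iqr: 14.0, family: normal}
      updrs3:         {median: 5.5,  iqr: 7.3,  family: lognormal, integer: true, clip: [0, 132]}
      brady:          {median: 4.0,  iqr: 6.0,  family: lognormal, integer: true, clip: [0, 44]}
      mmse:           {median: 28.0, iqr: 2.0,  family: normal, integer: true, clip: [18, 30]}
      bdi:            {median: 1.0,  iqr: 6.0,  family: normal, integer: true, clip: [0, 63]}
      letter_height:  {median: 5.0,  iqr: 1.4,  family: lognormal}
      writing_area:   {median: 548.0, iqr: 286.0, family: lognormal}
      progressive_b:  {median: -0.06, iqr: 0.32, family: normal}
      drawing_area:   {median: 25.8, iqr: 28.0, family: lognormal}
      sbr_caudate:    {median: 2.58, iqr: 0.54, family: lognormal}
      sbr_antput:     {median: 2.50, iqr: 0.60, family: lognormal}
      sbr_postput_l:  {median: 2.17, iqr: 0.51, family: lognormal}
      sbr_postput_r:  {median: 2.22, iqr: 0.55, family: lognormal}
    categorical:
      sex: {M: 19, F: 19}
      handedness: {right: 35, left: 2, symmetrical: 1}
      levodopa: {"no": 38}
    rank_correlations:
      - [1.00, 0.00, 0.00, 0.00, 0.00]
      - [0.00, 1.00, 0.00, 0.00, 0.00]
      - [0.00, 0.00, 1.00, 0.80, 0.00]
      - [0.00, 0.00, 0.80, 1.00, 0.00]
      - [0.00, 0.00, 0.00, 0.00, 1.00]
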