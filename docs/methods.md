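# Methods

This note documents the statistical models, processing rules and design
choices implemented in `pametrics`, and what the synthetic-data generator
does and does not emulate.

## Measurement model and reliability statistics

Each questionnaire score is modelled with a one-way random-effects
decomposition: subject *i*'s observation at administration *j* is

    x_ij = mu_i + e_ij,   mu_i ~ F_between,   e_ij ~ N(0, sigma_e^2),

with two administrations (T0, T1) a few days apart. From the one-way ANOVA
mean squares (MSB between subjects, MSW within),

* **ICC(1,1)** = (MSB − MSW) / (MSB + MSW) for k = 2, which equals
  between-subject variance over total variance. The 95% CI uses the exact
  one-way F interval: with F = MSB/MSW on (n−1, n(k−1)) degrees of freedom,
  the bounds are (F/F_u − 1)/(F/F_u + k − 1) and
  (F·F_l − 1)/(F·F_l + k − 1), where F_u and F_l are the upper 97.5%
  quantiles with the two df orders. Negative ICC estimates are reported
  as computed (a truly null subject effect should be visible as a small
  negative estimate, not silently clamped); the between-variance component
  is truncated at zero only for variance-scale outputs.
* **SEM** = √MSW, the standard error of measurement.
* **SDD95** = 1.96 · √2 · SEM, the smallest difference between two
  administrations attributable to real change at 95% confidence.
* **range95** = 97.5th − 2.5th percentile of the pooled T0 ∪ T1 values
  (pooling both visits; percentiles by linear interpolation between order
  statistics — stated so results are exactly reproducible).
* **SDD95/range95** and **distinguishable steps** = round(range95/SDD95),
  rounded half away from zero; an instrument resolving ≥ 7 steps is
  conventionally considered able to detect change, and a ratio ≤ 0.20 is
  flagged `clinically_useful`.
* **Qualitative rating**: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤
  excellent. The published banding ("0.40–0.59", "0.60–0.74", "exceeding
  0.75") leaves the gaps [0.59, 0.60) and [0.74, 0.75); they are closed
  downwards (fair and good respectively).

Subjects with a missing value at either visit are excluded pairwise with a
warning; n ≥ 2 complete pairs are required.

## Questionnaire scoring

**AQuAA.** Entries carry category, activity token, days/week, minutes/day
and perceived intensity. Weekly minutes = days × minutes. The MET value
comes from an editable lookup keyed on (activity, intensity) with a
per-category fallback; how perceived intensity should interact with a
compendium value is not standardised, so here intensity *selects among*
plausible MET values for the activity (documented ambiguity — users can
replace the table). Band edges are half-open and lower-inclusive:
sedentary [0, 2), light [2, 4), moderate [4, 6.5), vigorous [6.5, ∞) METs,
which keeps the "< 2 MET is sedentary" rule exact. The total score is
Σ MET × weekly minutes over entries with MET ≥ 2 (MET·min/week).

**PASE.** Ordinal answers are converted with midpoint maps: frequency
seldom = 1.5, sometimes = 3.5, often = 6 days/week; duration < 1 h = 0.5,
1–2 h = 1.5, 2–4 h = 3, > 4 h = 5 hours/day; work hours map directly to
0.5/2.5/6.5/10 hours/week. The sum score is Σ weight × hours/week over
weighted items, with the externally published item weights shipped as
configuration (the scorer refuses to run without a weights mapping).
Sitting items and sitting-only work accrue sedentary minutes and never
enter the weighted sum.

*Known inconsistency.* Published cohort tables report PASE sum-score
medians near 86 alongside ~25 h/week of total activity, which is only
arithmetically consistent with an hours-per-**day** scoring convention;
the hours-per-week convention implemented here follows the instrument
description. Consequently a response inverted from a sum-score target of
~86 encodes only a few hours/week of activity, and end-to-end PASE
minute-scale outputs sit well below accelerometer minute totals. The
midpoint maps are config-overridable if a different convention is wanted.

## Accelerometer processing

15-s vertical-axis epochs are summed 4-at-a-time into counts/min (streams
are trimmed to a minute boundary; a trailing partial minute is dropped
with a warning). **Non-wear** is every maximal run of ≥ 60 consecutive
zero-count minutes — strict zeros, no spike allowance, and the whole
maximal run is flagged. **Intensity** uses the Freedson uniaxial
cut-points: < 100 sedentary, 100–1951 light, 1952–5724 moderate, ≥ 5725
vigorous counts/min. A day is **valid** with ≥ 600 wear minutes; a subject
is **included** with ≥ 5 valid days of 7. Weekly minutes per band are the
mean over valid days × 7 (the only scale-consistent choice when 5 or 6
days are valid); overall counts/min is total counts over wear minutes of
valid days. Non-wear minutes are excluded from *all* bands (wear-time-only
accounting; whether off-body time should count as sedentary is
undecidable from zeros alone), so per-day band minutes sum exactly to wear
minutes. The "600 minutes" threshold is applied to wear minutes, not
recorded minutes. Journal-reported off-body intervals can optionally force
minutes to non-wear before summarising.

## Construct validity

Spearman rank correlations (average ranks for ties; p from the t
approximation on n−2 df, with optional Monte-Carlo or exact permutation p
for small n) compare questionnaire totals with overall counts/min.
Minute-scale outcomes are compared by the same one-way ICC machinery,
treating questionnaire and accelerometer as two replicate measurements.
Only accelerometer-included subjects enter. ACSM non-compliance is the
fraction with < 150 moderate-to-vigorous min/week (exactly 150 complies).

## Synthetic-cohort generator

The generator emulates a small mixed-cancer cohort (default n = 50)
answering both questionnaires twice five days apart and wearing an
accelerometer for 7 days.

**Latent scores.** Each primitive score (AQuAA light, MVPA, sedentary;
PASE sum, sedentary) draws its subject-level truth from a **Gamma**
distribution fitted to a target interquartile range, with additive normal
error whose SD is derived from a target population ICC:
sigma_e² = var_between · (1 − ICC)/ICC. Defaults are calibrated to
published quartiles and reliabilities for these instruments in cancer
patients (e.g. PASE sum IQR 49–161 at ICC 0.89). A Gamma was chosen over
a lognormal because weekly-minute scores are bounded (≤ 10080 min/week)
and a lognormal matched to the same quartiles implies far heavier upper
tails than plausible data, inflating the sampling spread of downstream
ICC estimates beyond what normal-theory CIs describe. Sedentary scores
use the *negated* activity latent (more active subjects sit less). All
scores share one activity latent per subject, so between-score rank
correlations are perfect — a simplification real cohorts do not show.

**Response inversion.** Scores are not emitted as numbers: AQuAA targets
become marker-activity entries (7 days/week, rounded minutes/day; each
band round-trips within 3.5 min/week), and PASE targets become ordinal
answers via greedy largest-fit over the category grid (residual below the
smallest item increment, ~15 score units). This exercises the scorers
end-to-end but adds discretisation error on top of the configured error
SD, so end-to-end reliability estimates for coarse scores (especially the
single-item PASE sedentary measure) sit below the configured ICC.

**Epoch streams.** Each day is an overnight zero gap, a contiguous wear
window (default 810 min starting 07:30 — matching published wear totals of
~5700 min/week), and an evening gap. Wear minutes draw a band from
(0.763, 0.198, 0.037, 0.002) base weights, with the light weight scaled by
exp(0.35·z) and moderate/vigorous by exp(0.65·z) for activity latent z;
within-band counts/min are a zero-inflated uniform (sedentary), cut-point
offsets plus truncated Gammas (light, moderate) or an exponential tail
(vigorous); minutes split multinomially into four 15-s epochs. These
defaults reproduce cohort medians near 289 counts/min overall, ~1120
light, ~225 MVPA and ~4330 sedentary min/week. The implied ACSM
non-compliance is ~20–27%, lower than the ~38% reported in comparable
cohorts: quartile-based calibration cannot pin down the empirical lower
tail of MVPA. Planted non-wear blocks are exact zeros and validated
against overlap; a configured rank correlation between questionnaire
latent and accelerometer level is induced by a Gaussian copula (Pearson
parameter 2·sin(π·rho/6)).

**Reproducibility.** One global seed; every subject draws from its own
`SeedSequence([seed, 1, i])` substream (scores first, then epochs), so
cohorts are bit-identical under replay and a subject's data are invariant
to cohort size. `simulate_paired_scores` uses the identical scheme and
therefore matches the scores embedded in a full cohort.

**What passing tests do not show.** The generator's simplifications —
perfect between-score rank correlation, additive homoscedastic error, a
fixed wear window, the hours/week PASE convention — mean that passing
parameter-recovery and distributional tests demonstrates correctness of
the *statistical machinery* under the stated model, not that the model
captures all features of real patient data (reactivity, day-of-week
structure, heteroscedastic recall error, item-level missingness).

## Numerical choices and problem sizes

Percentiles everywhere use linear interpolation; steps round half away
from zero; MSW = 0 degenerates to ICC 1 with CI [1, 1]; a zero observed
range reports the SDD ratio as missing rather than infinite. Simulation
tests use 200–500 replicates at n = 50 (the target cohort size) and
single large-n checks (n = 2000) for consistency; the exhaustive
ICC-oracle sweep covers all 65536 four-subject integer datasets with
values in {0..3}.
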