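# Methods

## The likelihood-ratio score

The score treats the four echocardiographic predictors as conditionally
independent diagnostic tests. A fetus referred for cardiac asymmetry carries
pre-test odds of CoAo equal to the class ratio of the derivation cohort,
41/44. Dichotomising each predictor at its published cut-off (boundary
inclusive, exactly as the cut-offs are printed: ≤ 28 weeks, ≤ −1.5, ≤ −2,
≥ 1.6) selects either the positive or the negative likelihood ratio, and the
post-test odds are the product of the pre-test odds and the four applied
LRs; probability = odds/(odds + 1).

Numerical choices:

- **Pre-test odds at full precision.** The odds are carried as 41/44
  (≈ 0.931818…), never as the two-decimal display value 0.93. Rounding
  before the multiplication changes the fourth significant digit of every
  output; the display layer rounds only for presentation.
- **Missing parameters.** Strict mode (default) raises an error naming the
  first unresolvable parameter. An explicit `missing="neutral"` opt-in
  substitutes LR = 1 for an absent parameter and flags the result as
  partial. Silent imputation is never performed, because the score was
  designed and validated with all four parameters present.
- **LR confidence intervals** are stored on the model for reporting but are
  not propagated into probability intervals; no propagation method is
  defined for the score.
- **Discreteness.** With four binary criteria the score attains exactly 16
  values (≈ 0.0261 … ≈ 0.9732 on the default model); `enumerate_profiles`
  is the package's own oracle for every cohort-level analysis. The printed
  operating points of the original validation (53%, 35%, 96%) are not all
  exactly attainable from the published two-significant-figure LRs — the
  nearest attainable values differ by up to ~1.5 percentage points,
  suggesting unrounded LRs were used upstream. This package uses the LRs
  exactly as published and reports thresholds as attained values plus a
  half-to-even rounded display percent.
- **Gestational dating.** The scoring GA is the decimal GA (weeks + days/7)
  at the first diagnostic echocardiography. `resolve_gestational_dating`
  implements the dating rule: ultrasound (crown–rump length) dating is used
  when the last menstrual period is unreliable or disagrees with it by
  strictly more than 7 days; a 7-day discordance exactly keeps the LMP.

## Z-score references

Published normative equations for fetal cardiac dimensions differ in
functional form and are not redistributable here, so the module is a
framework: a reference is a polynomial mean and polynomial SD on the
identity or natural-log scale of the measurement, against gestational age
(or femur length), valid over a declared predictor range, serialised as
JSON. The SD polynomial must be strictly positive over the declared range
(checked on a 101-point grid at construction). The packaged coefficients
(`data/synthetic_zrefs.json`, ids prefixed `synthetic-`) are plausible
GA-linear fixtures for testing and simulation only — clinical use requires
loading published coefficients through the same format. Explicitly provided
z-scores are never overwritten by `attach_zscores`.

## Validation pipeline

- **ROC/AUC.** Thresholds are the distinct attained predicted
  probabilities; "≥ threshold" predicts CoAo. The AUC is the Mann–Whitney
  form U/(n₁·n₀) with ties counted ½, computed via midranks; it equals the
  trapezoidal integral of the empirical curve to machine precision (a
  property test enforces 1e−12 agreement). The 95% CI is DeLong's
  variance-of-placement estimator, clipped to [0, 1]; no pre-installed
  package provides it, so it is implemented here and the point AUC is
  cross-checked against scikit-learn in the test suite.
- **Operating points.** "Best balance" is the Youden index maximum
  (J = Sn + Sp − 1), tie-broken toward higher specificity — fewer false
  referrals, matching the score's clinical motivation. Maximum sensitivity
  takes, among thresholds attaining the top sensitivity, the most specific
  one; maximum specificity takes, among thresholds attaining the top
  specificity with non-zero sensitivity, the most sensitive one.
- **Proportion CIs** are Wilson score intervals (via statsmodels). Wilson
  was chosen because it is well-behaved at 0 and 1 and matches the
  asymmetric-around-100% interval shape that diagnostic-accuracy tables in
  this literature display.
- **Probability bands** are half-open: [0, low), [low, high), [high, 1],
  with defaults 0.35 and 0.96 — the clinically quoted "reassurance" and
  "near-certainty" edges. A value exactly at an edge belongs to the upper
  band.
- **Group comparisons.** Continuous variables use Welch's t-test when both
  outcome groups pass a Shapiro–Wilk screen at α = 0.05, otherwise
  Mann–Whitney; categorical variables use Pearson's chi-square unless any
  expected cell count is below 5, then Fisher's exact test. A variable
  constant across both groups is flagged degenerate rather than assigned a
  p-value. All p-values are two-sided.
- **Subgroups.** Early vs late onset splits at GA ≤ 28 weeks, inclusive on
  the early side. A subgroup with a single outcome class gets a note
  instead of an undefined ROC.

## Synthetic cohort generator

The generator emulates the *structure* of a prospective cardiac-asymmetry
cohort so that every pipeline stage is exercisable without patient data:

- outcome drawn Bernoulli(prevalence = 0.218);
- onset drawn per class — early fraction 34/39 for CoAo and 34/140 for
  non-CoAo, reproducing both the overall 68/179 early share and the strong
  early-onset enrichment of true coarctation;
- GA from truncated normals: early ~ N(24, 3²) on [17, 28], late
  ~ N(33, 2.5²) on [28.1, 39] (overall mean ≈ 29.6 weeks, range 17–39);
- class-conditional z-scores (AAo: −2.2 ± 1.0 vs −0.8 ± 1.0; isthmus:
  −2.5 ± 1.0 vs −1.2 ± 1.2) and lognormal valve/vessel ratios (PV/AV
  medians 1.75 vs 1.35, TV/MV 1.60 vs 1.25, MPA/AAo 1.90 vs 1.40);
- raw diameters back-filled from the drawn z-scores and ratios through the
  synthetic references (AV from its GA-linear baseline, PV = ratio × AV,
  etc.) so comparator rules that consume millimetres run on the same
  records;
- qualitative findings generated but not score-relevant: PLSVC ≈ 14.5%
  overall in both classes; redundant foramen ovale flap enriched in
  late-onset non-CoAo fetuses (22% vs ≤ 5% elsewhere), mirroring its
  reported role as a CoAo mimic; aortic-arch flow antegrade in ~92%.

Class-conditional SDs and several rule-specific fields (isthmo-ductal
angle, CSA index, RV/LV) are plausibility choices — the source cohort's
summaries do not determine them — and are recorded as such in the
simulation manifest. The calibration targets the published *marginal*
summaries; reproducing the original cohort's exact group means or AUC is
explicitly not claimed, since that would be circular. Under the default
calibration the CoAo class's mean scored probability exceeds the non-CoAo
class's by well over 30 percentage points and the cohort AUC lands in the
mid-0.9s, the regime the analysis assumes.

Reproducibility: one `numpy` Generator seeded from the config; every record
consumes the same fixed sequence of draws (outcome, onset, GA quantile,
five z-scores, four log-ratios, two baseline noises, DA z, angle, CSA,
six uniforms for qualitative findings, velocity, one uniform for arch
hypoplasia) regardless of configuration values. Consequently cohorts are
bitwise reproducible, and configurations sharing a seed share their
underlying standard-normal draws — shifting a class mean moves every
affected record monotonically, which is what makes the
AUC-vs-class-separation monotonicity property deterministic.

The generator models only the first diagnostic exam; serial growth across
follow-up scans is out of scope. Exclusion flags (chromosomal abnormality,
growth restriction, associated major CHD, extrinsic compression, lost
follow-up) default to false in generated cohorts; `apply_inclusion_criteria`
filters externally supplied cohorts by the study's eligibility rules, with
the first matching flag recorded as the exclusion reason.

**What passing tests do and do not show.** The suite demonstrates that the
arithmetic, the ROC machinery and the reporting are correct, and that the
pipeline recovers the parameters of data generated under its own
assumptions. It does not show that real fetuses follow class-conditional
normal/lognormal distributions, that the four predictors are conditionally
independent (the LR product assumes this), or that the published LRs
transport to other populations.

## Comparator rules

Alternative published predictors are implemented only where the source
states a complete decision procedure (thresholds *and* aggregation): the
two onset-specific threshold pairs, the three-criterion late-onset rule,
the ≥ 2-of-4 rule, the 8-point score (positive at ≥ 4), the
diastolic-flow + MPA/AAo rule, and the CSA/composite-index rule (whose two
sub-rules are also registered individually, as their accuracies were
reported separately). The likelihood-ratio score itself joins the registry
thresholded at its recommended ≥ 53% operating point. Rules published as
parameter lists without combination logic or coefficients are registered
as descriptive-only and raise rather than guess. The MPA/AAo ≤ 0.65
criterion is implemented exactly as printed although its direction is
inconsistent with right dominance; the prediction detail carries a warning,
and on generated cohorts the rule's sensitivity is accordingly near zero.
Evaluating a rule on an exam lacking a required measurement is an error
naming the missing fields, never a silent negative.

## Problem sizes

Defaults used by the tests and the acceptance script: the study-scale
cohort is n = 179; parameter-recovery checks use n = 5,000; the binomial
prevalence bound uses n = 10,000; AUC-monotonicity uses n = 1,500 per grid
point; the tie-handling equivalence sweep uses 500 random cohorts. These
sizes give 3-standard-error margins comfortably tighter than the effects
being checked while keeping the default suite fast.

## Known limitations

- The conditional-independence assumption behind multiplying four LRs is
  inherited from the score, not tested here.
- The packaged z-score references are synthetic; z-dependent results are
  only as good as the references supplied.
- DeLong CIs are asymptotic; at very small n or AUC near 1 the clipped
  interval can be conservative.
- The generator draws measurements independently within a class (beyond the
  deterministic ratio back-fill), so it understates the correlation
  structure of real echocardiographic measurements.
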