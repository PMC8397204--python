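# coascore

Likelihood-ratio multiparameter scoring of fetal **coarctation of the aorta
(CoAo)** risk, with the full validation analytics and a synthetic cohort
generator.

## The problem

Prenatal suspicion of CoAo rests on an indirect sign — cardiac asymmetry with
right dominance — whose positive predictive value is poor, especially in the
third trimester: more than half of suspected cases are not confirmed after
birth, yet all are typically referred for tertiary-centre delivery. A
multiparameter score that separates the fetuses who truly have CoAo from the
false positives directly reduces unnecessary referrals and parental anxiety.

`coascore` is written for fetal-medicine researchers and biostatisticians who
want to apply such a score, audit its arithmetic, or evaluate it (and its
published competitors) on their own or simulated cohorts.

## The score

For a fetus referred with cardiac asymmetry, four dichotomised
echocardiographic predictors update the baseline odds of CoAo by Bayes'
theorem with likelihood ratios:

| parameter | criterion | LR+ | LR− |
|---|---|---|---|
| gestational age at diagnosis | ≤ 28 weeks | 4.3 | 0.3 |
| ascending-aorta z-score | ≤ −1.5 | 2.8 | 0.4 |
| aortic-isthmus z-score (3VT view) | ≤ −2 | 1.8 | 0.6 |
| PV/AV diameter ratio | ≥ 1.6 | 1.8 | 0.4 |

```
post-test odds        = pre-test odds × LR₁ × LR₂ × LR₃ × LR₄
post-test probability = odds / (odds + 1)
```

with pre-test odds 41/44 (≈ 0.93), the CoAo vs no-CoAo counts of the score's
derivation cohort. Each met criterion applies its LR+, each unmet one its
LR−, so the score takes exactly 2⁴ = 16 values between ≈ 2.6% and ≈ 97.3%.

Around the score the package provides: empirical ROC curves with
Mann–Whitney AUC and DeLong 95% CIs, operating-point selection (Youden best
balance, maximum sensitivity, maximum specificity), 2×2 diagnostic metrics
with Wilson score intervals, early/late-onset (≤ 28 vs > 28 weeks) subgroup
analysis, probability-band summaries, standard two-group comparisons, a
pluggable polynomial z-score reference framework, implementations of the
fully specified alternative published rules, and a seeded synthetic cohort
generator so the whole pipeline runs with no patient data.

## Worked example

```python
from coascore import FetalEchoExam, default_model, score_exam

exam = FetalEchoExam(ga_weeks=24.0, aao_z=-2.1, isthmus_3vt_z=-2.4,
                     pv_mm=6.0, av_mm=3.2)   # PV/AV = 1.875
result = score_exam(exam, default_model())
```

Running `python examples/score_single_exam.py` prints:

```
pre-test odds : 0.9318 (displayed 0.93)
  ga_weeks             criterion met      LR applied = 4.3
  aao_zscore           criterion met      LR applied = 2.8
  isthmus_3vt_zscore   criterion met      LR applied = 1.8
  pv_av_ratio          criterion met      LR applied = 1.8
post-test odds        : 36.3499
post-test probability : 0.9732 (97.0%)
```

All four criteria are met, so the pre-test odds are multiplied by every LR+:
0.9318 × 4.3 × 2.8 × 1.8 × 1.8 ≈ 36.35, a 97.3% probability that coarctation
will be confirmed after birth — the highest value the score can emit.

The other scripts in `examples/` each demonstrate one capability
(enumerating the 16 score values, simulating and validating a study-like
cohort, benchmarking comparator rules, deriving z-scores from raw
diameters). A thin CLI mirrors the library:

```sh
coascore simulate --paper-like --seed 7 --out cohort.csv
coascore predict  --cohort cohort.csv --out scored.csv
coascore validate --cohort cohort.csv --out report.json
coascore compare  --cohort cohort.csv --out benchmark.json
```

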