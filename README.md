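# lungscreen

Tools for evaluating lung cancer screening eligibility policies — rule-based
criteria versus risk-model-based selection — and the racial/ethnic
disparities they induce, for epidemiologists and biostatisticians working
with multiethnic ever-smoker cohorts.

## What it computes

**Risk scoring.** A participant's 6-year absolute risk of incident lung
cancer comes from a logistic model of the PLCOm2012 family:

```
logit P(case) = β₀ + β_age(age−62) + β_edu(edu−4) + β_bmi(BMI−27)
              + β_copd·COPD + β_ca·prior-cancer + β_fam·family-history
              + β_cur·current-smoker + β_int((cpd/10)⁻¹ − c)
              + β_dur(dur−27) + β_quit(quit−10) + β_race
```

Coefficient sets are versioned YAML data files (original, merged-race, and
any recalibrated update), consumed by a single evaluator.

**Recalibration.** The race/ethnicity-related parameters (an intercept
shift δ₀ plus one δ_r per non-reference group) are re-estimated on a target
cohort by an offset-logistic maximum-likelihood fit, with every other
coefficient frozen:

```
logit P(case) = offset + δ₀ + Σ_r δ_r · 1[race = r]
```

where `offset` is the base model's linear predictor. A 10-fold
outcome-stratified cross-validation harness provides out-of-fold risks for
honest validation (AUC with bootstrap CI, decile calibration slope, Brier
score), stratified by race.

**Eligibility.** Age/smoking rules (2021: age 50–80, ≥ 20 pack-years,
current or quit ≤ 15 y; 2013: age 55–80, ≥ 30 pack-years) and risk-threshold
criteria (risk ≥ t within ages 50–80), plus the order-statistic threshold
that matches a rule's eligible count.

**Disparity.** The eligibility-incidence (E-I) ratio per group — eligible
participants per incident 6-year case — compared with a reference group via
percent differences on rounded ratios and an offset Poisson rate-ratio Wald
test with Bonferroni correction; screening sensitivity, specificity and
number needed to screen (NNS) per group.

**Synthetic cohorts.** A generator emulating a five-group multiethnic
ever-smoker cohort (configurable group mix, per-group age/BMI/education/
smoking distributions) with outcomes drawn from a known risk model whose
intercept is tuned by bisection to a target incidence — so every estimator
can be checked against known truth.

## Worked example

`python examples/06_disparity.py` recomputes the E-I disparity table from
the packaged group-counts table of a 105 261-member multiethnic cohort:

```
2021 age/smoking rule
group                     E     I    E-I   % diff          p
african_american       4115   432    9.5    -53.2    <1e-300
japanese_american      6932   315   22.0     +8.4   2.52e-07
latino                 3360   159   21.1     +3.9   3.70e-02
nhpi                   2104   125   16.8    -17.2   2.37e-14
white                  8771   433   20.3     +0.0   1.00e+00

risk-based (6-year risk >= 1.3%)
group                     E     I    E-I   % diff          p
african_american       6879   432   15.9    -13.6   6.08e-18
japanese_american      5837   315   18.5     +0.5   5.83e-01
latino                 2549   159   16.0    -13.0   2.72e-09
nhpi                   2071   125   16.6     -9.8   3.28e-05
white                  7948   433   18.4     +0.0   1.00e+00
```

Reading it: under the age/smoking rule, 9.5 African American participants
are screening-eligible per incident case versus 20.3 among White
participants — a 53% lower E-I ratio, i.e. far less screening per case of
disease. Risk-based selection at the eligibility-matched 1.3% cutoff closes
most of that gap (15.9 vs 18.4) while leaving other groups close to the
reference.

The other examples cover single-record scoring (`01`), cohort simulation
(`02`), recalibration recovery of injected race effects (`03`),
cross-validated per-race validation metrics (`04`), and eligibility-matched
threshold selection (`05`). The full pipeline is also scriptable:

```
lungscreen disparity --counts packaged --out results/
lungscreen run --config pipeline.yaml --seed 7 --out results/
```

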