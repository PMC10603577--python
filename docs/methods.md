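# Methods

## The model and the question

The package evaluates who a lung cancer screening policy selects, relative
to where the disease burden actually falls, across racial/ethnic groups in
an ever-smoker cohort followed for six years. Two policy families are
implemented: age/smoking rules (an age window, a minimum cumulative
pack-year exposure, and a maximum time since cessation for former smokers)
and risk-based selection, which screens everyone whose predicted 6-year
absolute risk reaches a cutoff, restricted to the rule-defined age window
(50–80, bounds inclusive; eligibility is assessed once, at enrollment
covariate values).

Absolute risk comes from a logistic model of the PLCOm2012 family:
centered age, education (ordinal 1–6), BMI, indicators for COPD/emphysema,
personal cancer history, family history of lung cancer and current
smoking, a reciprocal transform of smoking intensity ((cigarettes/day ÷
10)⁻¹, centered — risk rises steeply at low intensities and flattens at
high ones), centered smoking duration and quit-years, and a race/ethnicity
coefficient with White as reference. Coefficients live in versioned YAML
files, never in code, so the original published set, a merged-race variant
and any cohort-specific update are all data consumed by one evaluator. The
merged-race variant maps Japanese American, Latino and NHPI onto the White
reference via an explicit merge table rather than duplicated zero
coefficients, keeping "exactly one reference" checkable.

## Recalibration

When the original model is mis-calibrated for particular groups in a new
cohort, only its race/ethnicity-related parameters are re-estimated: with
the base model's full linear predictor as a fixed offset, the working model
is `logit P = offset + δ₀ + Σ δ_r·1[race=r]`, reference δ = 0. The δ's are
therefore *shifts* of the base race coefficients (data generated by the
base model itself recovers δ ≈ 0), and the updated coefficient set differs
from the base only in intercept (+δ₀) and race coefficients (+δ_r). The
intercept shift is included so calibration can improve for the reference
group too, which pure race indicators cannot do.

The fit is exact maximum likelihood by damped Newton/IRLS on the small
(1 + R−1)-parameter problem: full Newton steps, halved whenever a step
would decrease the log-likelihood (undamped Newton can overshoot into
weight underflow on small strata), gradient-norm tolerance 1e-8, at most
100 iterations, no regularization. Standard errors come from the inverse
observed information. A race category with zero or all events on the
fitting data is separated: it is flagged, its estimate reported as NaN, its
rows dropped from the fit, and the updated model keeps the base
coefficient for it — the run is not fatal.

Cross-validation stratifies folds by outcome (falling back to unstratified
folds with a warning when a class is smaller than the fold count, e.g.
leave-one-out); each record's risk is predicted by the recalibration
fitted on the other folds, so validation metrics never reuse the data that
tuned the race parameters. The partition is deterministic given its seed.

## Validation metrics

AUC is the rank-statistic form (ties count one half), identical to the
probability that a random event outranks a random non-event; its CI is a
seeded stratified percentile bootstrap (2000 replicates by default,
resampling events and non-events separately) — chosen over asymptotic
formulas for uniform behavior across very different group sizes.
Calibration sorts records by predicted risk (stable sort, so tied scores
are split by record order) and cuts them into near-equal decile bins — the
inverse-ECDF quantile convention; the calibration slope is the OLS slope
of observed event proportions on mean predicted risk across bins (1 =
perfect, > 1 = under-estimation of risk). Fewer distinct scores than bins
reduces the bin count with a warning. The Brier score is the mean squared
difference between predicted probability and outcome.

## Eligibility-matched thresholds

To compare a risk-based policy with a rule at equal program size, the risk
cutoff is the k-th largest in-age-window risk, where k is the rule's
eligible count — the largest threshold whose eligible count is at least k.
Matching is done on counts, not percentages, to avoid rounding ambiguity;
with ties at the cutoff the risk-eligible count can exceed k (documented
tie inflation). A target of zero returns an infinite sentinel.

## Disparity analysis

The E-I ratio of a group is its screening-eligible count divided by its
incident 6-year case count; cases need not themselves be eligible, which
is exactly why the ratio captures under-service: a group can contribute
many cases while qualifying rarely. Group-vs-reference percent differences
are computed on one-decimal-rounded ratios — reporting convention chosen so
printed percent differences are reproducible from printed ratios. Formal
comparison uses a two-group Poisson model for eligible counts with
log(cases) as offset; the MLE is closed form (rate ratio = ratio of E-I
ratios, SE of the log rate ratio = √(1/E₁ + 1/E₂)), giving a two-sided
Wald test, flagged at the Bonferroni level 0.05/4 = 0.0125 for the four
non-reference comparisons. A likelihood-ratio oracle backs the Wald test in
the test suite; the two agree closely near the null but genuinely diverge
for strong effects, which is a property of Wald inference, not an
implementation artifact. Screening performance per group: sensitivity =
eligible cases / all cases, specificity = ineligible non-cases / all
non-cases, NNS = eligible participants / eligible cases (reported raw and
rounded half-away-from-zero to an integer).

## Synthetic cohorts

The generator emulates a five-group multiethnic ever-smoker cohort
enrolled at ages 45–75. Defaults reproduce published enrollment marginals
of such a cohort: group mix (18.3 / 25.9 / 20.3 / 7.9 / 27.6% for African
American / Japanese American / Latino / NHPI / White), per-group age and
BMI means/SDs, sex ratios, six-level education distributions,
current-smoker fractions, smoking intensity and duration moments,
quit-year means, and prevalences of personal cancer history and family
history. Shapes are implementation choices where only moments are known:
truncated normals for age, BMI, intensity (floor 1 cigarette/day) and
duration (floored at 1 year, capped at age − 19 so smoking cannot start
before 18); quit-years for former smokers from an exponential truncated at
age − 18 − duration. COPD/emphysema prevalence is not part of the published
marginals; it defaults to 10% of ever-smokers, a realistic figure, and is
configurable. Pack-years are derived as intensity/20 × duration.

Outcomes are Bernoulli draws from a declared "true" coefficient set (the
packaged original model by default) whose intercept is shifted by
bisection so the cohort's expected incidence hits the 1.4% target (the
tuned offset is recorded on the frame's attrs so tests can reconstruct the
exact generating model). Correlations between covariates beyond those
induced by group membership and the derived pack-years are *not* modeled,
and neither are calendar time, geography, or death as a competing risk.
Consequently passing recovery and calibration tests shows the estimators
are correct under the declared generating process — not that any particular
real cohort satisfies that process; rule-eligibility percentages in
synthetic cohorts run a few points higher than real enrollment tables
because intensity and duration are drawn independently.

## Cohort data handling

Cohorts are pandas DataFrames with a canonical column set; delimited-text
readers accept a user-supplied header map. Rows are rejected (with reason
codes, not fatally) for missing race, missing smoking data, never-smoker
status, or a stated pack-year value inconsistent with intensity/20 ×
duration beyond 15% relative; absent pack-years are derived by that
formula. Current smokers have quit-years coerced to zero with a logged
repair count; a missing COPD column is imputed false with a logged count,
since the risk model requires the flag — a documented guess, flagged at
read time, not an assertion about how any source cohort measured it.
Group-counts tables validate that every overall entry equals the sum over
groups and name the offending column otherwise.

## Determinism and problem sizes

All randomness flows from explicit seeds; the pipeline expands one root
seed per stage through a hash, and re-running a configuration reproduces
every output byte-identically (wall-clock timing goes to the log, never
into outputs). Stochastic test fixtures use n = 100 000 for recovery and
calibration checks — large enough that the ±0.15 recovery tolerance at
~1.4% prevalence follows from binomial information — and n = 5 000–50 000
for integration checks. Precision notes: the logit/logistic round trip is
exact to 1e-12 only where 1 − p is well conditioned (lp ≲ 5 in float64);
E-I ratios are rounded half-away-from-zero to one decimal before percent
differences, matching the reporting convention.

## Known limitations

Only the race-related parameters can be recalibrated — no shrinkage, no
refitting of smoking coefficients. The Poisson comparison is the two-group
offset model without further covariates. The packaged merged-race
coefficient file implements the documented category merge on the original
coefficients; it is not a refit. Coefficient values for other published
risk models (LCRAT, Bach, LLPv3) are not packaged, though the coefficient
file interface admits any model of this functional form.
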