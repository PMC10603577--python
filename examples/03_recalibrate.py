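"""Re-estimate the race/ethnicity parameters of the risk model on a cohort
whose true race effects differ from the base model, keeping every other
coefficient frozen.

Here the generating model shifts the African American log-odds by +0.5 and
the Latino log-odds by -0.4 relative to the base model; the offset-logistic
recalibration should recover those shifts.
"""

from lungscreen import CoefficientSet, fit_race_recalibration, load_original_model
from lungscreen.synthetic_cohort import SyntheticSpec, generate_cohort

base = load_original_model()
shifts = {"african_american": +0.5, "latino": -0.4}

race = dict(base.race_coefficients)
for group, d in shifts.items():
    race[group] += d
truth = CoefficientSet("shifted-truth", base.intercept, base.terms, race)

cohort = generate_cohort(SyntheticSpec(n=100_000, seed=11, true_model=truth))
# put the incidence-tuning intercept offset into the base so only the race
# effects differ between base model and truth
base = base.with_race_update(
    cohort.attrs["true_intercept_offset"], base.race_coefficients, "-tuned"
)

fit = fit_race_recalibration(cohort, base)
print(f"converged in {fit.n_iterations} Newton iterations\n")
print(f"{'parameter':<20}{'estimate':>10}{'SE':>8}{'truth':>8}")
for name, (est, se) in fit.estimates.items():
    true_val = shifts.get(name, 0.0)
    print(f"{name:<20}{est:>10.3f}{se:>8.3f}{true_val:>8.1f}")
print()
print("Each estimate is the fitted shift of that group's race coefficient")
print("(0 = no change from the base model); the injected +0.5 and -0.4 are")
print("recovered within sampling error at n = 100 000, ~1.4% prevalence.")
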