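"""Synthetic multiethnic-cohort generator.

Emulates the covariate structure of a large multiethnic cohort of
ever-smokers (five racial/ethnic groups, ages 45-75 at enrollment) so that
risk scoring, recalibration, validation and the disparity analysis are all
testable without access to the study records.  Default per-group
parameters reproduce the published enrollment marginals: group mix, age
and BMI means/SDs, current-smoker fraction, education distribution,
smoking intensity / duration / quit-year moments, and flag prevalences.

Outcomes are drawn Bernoulli from a known "true" risk model (the packaged
original coefficient set by default) whose intercept is shifted by
bisection so the cohort's expected 6-year incidence hits a target (1.4%
by default).  Covariate correlations beyond those induced by group
membership and the derived pack-years are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import COHORT_COLUMNS, GroupCountsTable
from .eligibility import EligibilityCriterion, eligibility_summary
from .risk_models import CoefficientSet, linear_predictor, load_original_model, logistic


@dataclass(frozen=True)
class RaceParams:
    """Per-group covariate distribution parameters (enrollment marginals)."""

    age_mean: float
    age_sd: float
    male_prob: float
    current_smoker_prob: float
    intensity_mean: float
    intensity_sd: float
    duration_mean: float
    duration_sd: float
    quit_years_mean: float  # former smokers; exponential, truncated
    bmi_mean: float
    bmi_sd: float
    education_probs: tuple[float, ...]  # levels 1..6
    cancer_history_prob: float
    family_history_prob: float
    copd_prob: float = 0.10


def _norm(p: Sequence[float]) -> tuple[float, ...]:
    a = np.asarray(p, dtype=float)
    return tuple(a / a.sum())


#: Defaults matched to the published enrollment table, one entry per group.
DEFAULT_RACE_PARAMS: dict[str, RaceParams] = {
    "african_american": RaceParams(
        age_mean=61.0, age_sd=8.9, male_prob=0.445, current_smoker_prob=0.375,
        intensity_mean=12.5, intensity_sd=7.1, duration_mean=23.6, duration_sd=12.3,
        quit_years_mean=7.6, bmi_mean=28.2, bmi_sd=5.7,
        education_probs=_norm([15.1, 27.8, 6.3, 30.9, 10.4, 9.5]),
        cancer_history_prob=0.100, family_history_prob=0.063,
    ),
    "japanese_american": RaceParams(
        age_mean=60.6, age_sd=8.9, male_prob=0.675, current_smoker_prob=0.241,
        intensity_mean=16.0, intensity_sd=8.0, duration_mean=22.6, duration_sd=12.2,
        quit_years_mean=10.8, bmi_mean=24.9, bmi_sd=3.7,
        education_probs=_norm([8.7, 30.4, 13.2, 19.0, 17.8, 10.8]),
        cancer_history_prob=0.071, family_history_prob=0.068,
    ),
    "latino": RaceParams(
        age_mean=59.9, age_sd=7.6, male_prob=0.655, current_smoker_prob=0.289,
        intensity_mean=11.0, intensity_sd=7.3, duration_mean=20.5, duration_sd=13.0,
        quit_years_mean=9.3, bmi_mean=27.8, bmi_sd=4.8,
        education_probs=_norm([43.4, 24.1, 6.7, 16.3, 4.9, 4.7]),
        cancer_history_prob=0.062, family_history_prob=0.040,
    ),
    "nhpi": RaceParams(
        age_mean=56.2, age_sd=8.4, male_prob=0.493, current_smoker_prob=0.380,
        intensity_mean=15.9, intensity_sd=8.2, duration_mean=23.1, duration_sd=12.0,
        quit_years_mean=7.9, bmi_mean=29.1, bmi_sd=6.3,
        education_probs=_norm([14.5, 42.3, 7.8, 21.6, 8.0, 5.8]),
        cancer_history_prob=0.076, family_history_prob=0.076,
    ),
    "white": RaceParams(
        age_mean=59.1, age_sd=9.0, male_prob=0.514, current_smoker_prob=0.276,
        intensity_mean=17.6, intensity_sd=8.7, duration_mean=22.9, duration_sd=12.6,
        quit_years_mean=10.1, bmi_mean=26.2, bmi_sd=4.9,
        education_probs=_norm([7.1, 21.2, 4.5, 29.5, 18.3, 19.4]),
        cancer_history_prob=0.116, family_history_prob=0.077,
    ),
}

#: Group mix from the published row percentages.
DEFAULT_RACE_MIX: dict[str, float] = {
    "african_american": 0.183,
    "japanese_american": 0.259,
    "latino": 0.203,
    "nhpi": 0.079,
    "white": 0.276,
}


@dataclass
class SyntheticSpec:
    """Specification of one synthetic cohort draw."""

    n: int
    seed: int = 0
    race_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    race_params: Mapping[str, RaceParams] = field(
        default_factory=lambda: dict(DEFAULT_RACE_PARAMS)
    )
    true_model: CoefficientSet | None = None  # packaged original model if None
    target_incidence: float = 0.014
    age_range: tuple[float, float] = (45.0, 75.0)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        total = sum(self.race_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"race_mix sums to {total}, expected 1")
        for g, p in self.race_params.items():
            for sd in (p.age_sd, p.intensity_sd, p.duration_sd, p.bmi_sd):
                if sd <= 0:
                    raise ValueError(f"{g}: all SDs must be positive")
        if not (0.0 < self.target_incidence < 1.0):
            raise ValueError("target_incidence must be in (0, 1)")


class IncidenceTuningError(RuntimeError):
    """Bisection on the intercept offset failed to bracket the target."""


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Sample a normal truncated to [lo, hi] by per-draw inverse CDF."""
    from scipy import stats

    a = (np.asarray(lo) - mean) / sd
    b = (np.asarray(hi) - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def tune_intercept_offset(
    lp: np.ndarray, target: float, tol: float = 1e-10, max_iter: int = 200
) -> float:
    """Offset c with mean(logistic(lp + c)) = target, by bisection."""
    lo, hi = -30.0, 30.0
    f = lambda c: float(np.mean(logistic(lp + c))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise IncidenceTuningError(
            f"target incidence {target} not bracketed by intercept offsets "
            f"in [{lo}, {hi}] (mean risk range "
            f"[{f(lo) + target:.3g}, {f(hi) + target:.3g}])"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a cohort frame; deterministic given ``spec.seed``."""
    if spec.n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.race_mix)
    probs = np.array([spec.race_mix[g] for g in groups])
    race = rng.choice(np.array(groups, dtype=object), size=spec.n, p=probs)

    age = np.empty(spec.n)
    sex = np.empty(spec.n, dtype=object)
    education = np.empty(spec.n, dtype=int)
    bmi = np.empty(spec.n)
    copd = np.zeros(spec.n, dtype=bool)
    cancer_hist = np.zeros(spec.n, dtype=bool)
    family_hist = np.zeros(spec.n, dtype=bool)
    status = np.empty(spec.n, dtype=object)
    intensity = np.empty(spec.n)
    duration = np.empty(spec.n)
    quit_years = np.zeros(spec.n)

    lo_age, hi_age = spec.age_range
    for g in groups:
        idx = np.where(race == g)[0]
        if idx.size == 0:
            continue
        p = spec.race_params[g]
        age[idx] = _truncated_normal(rng, p.age_mean, p.age_sd, lo_age, hi_age, idx.size)
        sex[idx] = np.where(rng.uniform(size=idx.size) < p.male_prob, "male", "female")
        education[idx] = rng.choice(np.arange(1, 7), size=idx.size, p=p.education_probs)
        bmi[idx] = _truncated_normal(rng, p.bmi_mean, p.bmi_sd, 15.0, 60.0, idx.size)
        copd[idx] = rng.uniform(size=idx.size) < p.copd_prob
        cancer_hist[idx] = rng.uniform(size=idx.size) < p.cancer_history_prob
        family_hist[idx] = rng.uniform(size=idx.size) < p.family_history_prob
        cur = rng.uniform(size=idx.size) < p.current_smoker_prob
        status[idx] = np.where(cur, "current", "former")
        intensity[idx] = _truncated_normal(
            rng, p.intensity_mean, p.intensity_sd, 1.0, 80.0, idx.size
        )
        # smoking can't start before age 18 nor run past the year before enrollment
        dur_cap = np.maximum(age[idx] - 19.0, 1.0)
        duration[idx] = _truncated_normal(
            rng, p.duration_mean, p.duration_sd, 1.0, dur_cap, idx.size
        )
        former = idx[~cur]
        if former.size:
            cap = np.maximum(age[former] - 18.0 - duration[former], 0.5)
            u = rng.uniform(size=former.size)
            m = p.quit_years_mean
            quit_years[former] = -m * np.log1p(-u * (1.0 - np.exp(-cap / m)))

    pack_years = intensity / 20.0 * duration

    cohort = pd.DataFrame(
        {
            "id": [f"syn{spec.seed}_{i}" for i in range(spec.n)],
            "race_ethnicity": race,
            "age": age,
            "sex": sex,
            "education": education,
            "bmi": bmi,
            "copd_emphysema": copd,
            "personal_cancer_history": cancer_hist,
            "family_history_lung_cancer": family_hist,
            "smoking_status": status,
            "intensity": intensity,
            "duration": duration,
            "quit_years": quit_years,
            "pack_years": pack_years,
        },
        columns=[c for c in COHORT_COLUMNS if c != "lung_cancer_6yr"],
    )

    model = spec.true_model if spec.true_model is not None else load_original_model()
    lp = linear_predictor(cohort, model)
    offset = tune_intercept_offset(lp, spec.target_incidence)
    risk = logistic(lp + offset)
    cohort["lung_cancer_6yr"] = rng.uniform(size=spec.n) < risk
    cohort.attrs["true_intercept_offset"] = offset
    cohort.attrs["true_risk_mean"] = float(np.mean(risk))
    return cohort


def aggregate_counts(
    cohort: pd.DataFrame,
    criteria: Sequence[EligibilityCriterion] = (),
    scores=None,
) -> GroupCountsTable:
    """Aggregate an individual-level cohort to the group-counts shape."""
    return eligibility_summary(cohort, list(criteria), scores)
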