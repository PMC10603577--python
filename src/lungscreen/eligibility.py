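"""Screening-eligibility rules and risk-threshold eligibility.

Two kinds of criterion are supported:

* ``age_smoking_rule`` — an age window plus minimum pack-years plus a
  maximum number of quit-years for former smokers (current smokers always
  satisfy the cessation clause).  The 2021 national guideline is age 50-80,
  >= 20 pack-years, quit <= 15 years; the 2013 guideline is age 55-80,
  >= 30 pack-years, quit <= 15 years.
* ``risk_threshold`` — predicted 6-year risk at or above a probability
  cutoff, restricted to the rule-defined age window (50-80 by default).

All age bounds are inclusive at both ends and eligibility is assessed once,
at enrollment covariate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    OVERALL,
    RACE_CATEGORIES,
    GroupCountsTable,
    ParticipantRecord,
)
from .risk_models import RiskScore

#: Sentinel returned by :func:`match_threshold` when no one should qualify.
NO_ONE_ELIGIBLE = math.inf


@dataclass(frozen=True)
class EligibilityCriterion:
    """One screening-eligibility rule (age/smoking based or risk based)."""

    name: str
    kind: str  # "age_smoking_rule" | "risk_threshold"
    age_lo: float = 50.0
    age_hi: float = 80.0
    min_pack_years: float | None = None
    max_quit_years: float | None = None
    threshold: float | None = None
    model_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("age_smoking_rule", "risk_threshold"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not self.age_lo < self.age_hi:
            raise ValueError("age range must satisfy lo < hi")
        if self.kind == "age_smoking_rule":
            if self.min_pack_years is None or self.max_quit_years is None:
                raise ValueError("age_smoking_rule needs min_pack_years and max_quit_years")
        else:
            if self.threshold is None or not (0.0 < self.threshold < 1.0):
                raise ValueError("risk_threshold needs a threshold in (0, 1)")


USPSTF_2021_RULE = EligibilityCriterion(
    name="uspstf_2021", kind="age_smoking_rule",
    age_lo=50, age_hi=80, min_pack_years=20, max_quit_years=15,
)
USPSTF_2013_RULE = EligibilityCriterion(
    name="uspstf_2013", kind="age_smoking_rule",
    age_lo=55, age_hi=80, min_pack_years=30, max_quit_years=15,
)


def risk_criterion(
    threshold: float = 0.013,
    name: str | None = None,
    model_name: str | None = None,
    age_lo: float = 50.0,
    age_hi: float = 80.0,
) -> EligibilityCriterion:
    """Risk-based criterion: 6-year risk >= threshold within the age window."""
    if name is None:
        name = f"risk_{threshold:g}"
    return EligibilityCriterion(
        name=name, kind="risk_threshold", threshold=threshold,
        model_name=model_name, age_lo=age_lo, age_hi=age_hi,
    )


def is_eligible(
    record: ParticipantRecord,
    criterion: EligibilityCriterion,
    risk: RiskScore | float | None = None,
) -> bool:
    """Evaluate one record against one criterion.

    ``risk`` must be supplied iff the criterion is risk based; the threshold
    comparison is inclusive (risk equal to the cutoff qualifies).
    """
    if criterion.kind == "age_smoking_rule":
        if risk is not None:
            raise ValueError("risk supplied for an age/smoking rule")
        if record.pack_years is None or (
            isinstance(record.pack_years, float) and math.isnan(record.pack_years)
        ):
            raise ValueError(f"record {record.id}: pack_years missing")
        in_age = criterion.age_lo <= record.age <= criterion.age_hi
        enough_py = record.pack_years >= criterion.min_pack_years
        recent = (
            record.smoking_status == "current"
            or record.quit_years <= criterion.max_quit_years
        )
        return bool(in_age and enough_py and recent)
    if risk is None:
        raise ValueError("risk_threshold criterion needs a risk")
    r = risk.risk if isinstance(risk, RiskScore) else float(risk)
    return bool(
        criterion.age_lo <= record.age <= criterion.age_hi and r >= criterion.threshold
    )


def eligible_mask(
    cohort: pd.DataFrame,
    criterion: EligibilityCriterion,
    risks: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Vectorised eligibility over a cohort frame."""
    age = cohort["age"].to_numpy(dtype=float)
    in_age = (age >= criterion.age_lo) & (age <= criterion.age_hi)
    if criterion.kind == "age_smoking_rule":
        if risks is not None:
            raise ValueError("risk supplied for an age/smoking rule")
        py = cohort["pack_years"].to_numpy(dtype=float)
        if np.isnan(py).any():
            raise ValueError("pack_years missing for some records")
        recent = (cohort["smoking_status"].to_numpy() == "current") | (
            cohort["quit_years"].to_numpy(dtype=float) <= criterion.max_quit_years
        )
        return in_age & (py >= criterion.min_pack_years) & recent
    if risks is None:
        raise ValueError("risk_threshold criterion needs risks")
    r = np.asarray(risks, dtype=float)
    return in_age & (r >= criterion.threshold)


def match_threshold(
    risks: Sequence[float] | np.ndarray,
    ages: Sequence[float] | np.ndarray,
    target_count: int,
    age_lo: float = 50.0,
    age_hi: float = 80.0,
) -> float:
    """Risk cutoff whose in-age-window eligible count matches a target.

    Returns the ``target_count``-th largest risk among records inside the
    age window — the largest threshold t with ``#{risk >= t, in window} >=
    target_count``.  With tied risks at the cutoff the eligible count may
    exceed the target.  ``target_count = 0`` returns an infinite sentinel
    (no one eligible).
    """
    risks = np.asarray(risks, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if target_count == 0:
        return NO_ONE_ELIGIBLE
    in_window = risks[(ages >= age_lo) & (ages <= age_hi)]
    if target_count > in_window.size:
        raise ValueError(
            f"target_count {target_count} exceeds {in_window.size} in-window records"
        )
    return float(np.sort(in_window)[::-1][target_count - 1])


def eligibility_summary(
    cohort: pd.DataFrame,
    criteria: Sequence[EligibilityCriterion],
    scores: Mapping[str, np.ndarray | pd.Series] | np.ndarray | None = None,
) -> GroupCountsTable:
    """Per-race and overall eligible counts for every criterion.

    ``scores`` supplies per-record risks for risk-based criteria: either a
    single vector (shared by all risk criteria) or a map keyed by criterion
    name.
    """
    race = cohort["race_ethnicity"].to_numpy() if len(cohort) else np.array([])
    outcome = cohort["lung_cancer_6yr"].to_numpy(dtype=bool) if len(cohort) else np.array([], bool)

    def per_group(values: np.ndarray) -> dict[str, int]:
        col = {g: int(values[race == g].sum()) for g in RACE_CATEGORIES}
        col[OVERALL] = int(values.sum())
        return col

    n_total = {g: int((race == g).sum()) for g in RACE_CATEGORIES}
    n_total[OVERALL] = len(cohort)
    cases = per_group(outcome) if len(cohort) else {g: 0 for g in (*RACE_CATEGORIES, OVERALL)}

    eligible: dict[str, dict[str, int]] = {}
    for crit in criteria:
        if crit.kind == "risk_threshold":
            if scores is None:
                raise ValueError(f"criterion {crit.name!r} needs risks")
            r = scores[crit.name] if isinstance(scores, Mapping) else scores
        else:
            r = None
        mask = (
            eligible_mask(cohort, crit, r) if len(cohort)
            else np.array([], dtype=bool)
        )
        eligible[crit.name] = per_group(mask) if len(cohort) else {
            g: 0 for g in (*RACE_CATEGORIES, OVERALL)
        }
    return GroupCountsTable(n_total=n_total, incident_cases_6yr=cases, eligible=eligible)
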