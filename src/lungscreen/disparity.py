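"""Eligibility-incidence (E-I) ratio disparity analysis and screening
performance metrics.

The E-I ratio of a group is the number of screening-eligible participants
divided by the number of 6-year incident lung cancer cases in that group
(cases need not themselves be eligible).  A low ratio flags a group that is
under-served by the eligibility rule relative to its cancer burden.
Groups are compared with a reference group (White by default) via

* the percent difference of E-I ratios, computed on the one-decimal
  rounded ratios as reported, and
* a two-group Poisson model for eligible counts with the log of incident
  cases as offset, giving a rate ratio with a Wald test; significance is
  declared at the Bonferroni-adjusted level (0.05 / 4 comparisons by
  default).

Screening performance per group is sensitivity (eligible cases / all
cases), specificity (ineligible non-cases / all non-cases), and the number
needed to screen, NNS = eligible participants / eligible cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import OVERALL, AnalysisConfig, GroupCountsTable


def _round_half_away(x: float, digits: int = 1) -> float:
    """Round half away from zero (the convention used in reported ratios)."""
    f = 10.0**digits
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


@dataclass(frozen=True)
class EIResult:
    group: str
    criterion: str
    eligible: int
    incident_cases: int
    ei_ratio: float
    ei_ratio_rounded: float
    percent_difference_vs_reference: float | None
    rate_ratio: float | None
    wald_z: float | None
    p_value: float | None
    significant_after_bonferroni: bool | None


@dataclass(frozen=True)
class PerformanceResult:
    group: str
    criterion: str
    sensitivity: float  # percent
    specificity: float  # percent
    nns: float
    nns_rounded: int


def ei_ratio(eligible: int, cases: int) -> float:
    """Eligible participants per incident case (undefined when cases = 0)."""
    if cases <= 0:
        raise ValueError("E-I ratio undefined: no incident cases")
    if eligible < 0:
        raise ValueError("eligible count must be non-negative")
    return eligible / cases


def percent_difference(group_ratio: float, reference_ratio: float) -> float:
    """(group - reference) / reference x 100, on ratios rounded upstream."""
    if reference_ratio <= 0:
        raise ValueError("reference ratio must be positive")
    return (group_ratio - reference_ratio) / reference_ratio * 100.0


def poisson_compare(
    e1: int, i1: int, e2: int, i2: int
) -> tuple[float, float, float]:
    """Compare two E-I ratios via an offset Poisson model.

    Eligible counts are modelled as Poisson with log(incident cases) as
    offset; group 1 is the reference.  The closed-form MLE of the log rate
    ratio is log((e2/i2)/(e1/i1)) with standard error sqrt(1/e1 + 1/e2).

    Returns
    -------
    (rate_ratio, wald_z, p_value) — two-sided Wald test.
    """
    for name, v in (("e1", e1), ("i1", i1), ("e2", e2), ("i2", i2)):
        if v <= 0:
            raise ValueError(f"poisson_compare needs positive counts; {name}={v}")
    log_rr = math.log((e2 / i2) / (e1 / i1))
    se = math.sqrt(1.0 / e1 + 1.0 / e2)
    z = log_rr / se
    p = 2.0 * stats.norm.sf(abs(z))
    return math.exp(log_rr), z, p


def poisson_loglik(e1: int, i1: int, e2: int, i2: int, log_rr: float) -> float:
    """Profile log-likelihood of the two-group offset Poisson model at a
    fixed log rate ratio (nuisance base rate maximised out)."""
    # mu1 = lam*i1, mu2 = lam*exp(log_rr)*i2; lam-hat = (e1+e2)/(i1+exp(log_rr)*i2)
    w = math.exp(log_rr)
    lam = (e1 + e2) / (i1 + w * i2)
    mu1, mu2 = lam * i1, lam * w * i2
    return e1 * math.log(mu1) - mu1 + e2 * math.log(mu2) - mu2


def screening_performance(
    eligible_cases: int,
    total_cases: int,
    eligible_noncases: int,
    total_noncases: int,
    eligible_total: int,
    group: str = OVERALL,
    criterion: str = "",
) -> PerformanceResult:
    """Sensitivity, specificity (percent) and number needed to screen."""
    if not (0 <= eligible_cases <= total_cases):
        raise ValueError("eligible_cases must lie in [0, total_cases]")
    if not (0 <= eligible_noncases <= total_noncases):
        raise ValueError("eligible_noncases must lie in [0, total_noncases]")
    sens = 100.0 * eligible_cases / total_cases if total_cases else float("nan")
    spec = (
        100.0 * (total_noncases - eligible_noncases) / total_noncases
        if total_noncases
        else float("nan")
    )
    nns = eligible_total / eligible_cases if eligible_cases else float("inf")
    return PerformanceResult(
        group=group,
        criterion=criterion,
        sensitivity=sens,
        specificity=spec,
        nns=nns,
        nns_rounded=int(_round_half_away(nns, 0)) if math.isfinite(nns) else -1,
    )


def disparity_table(
    counts: GroupCountsTable,
    config: AnalysisConfig | None = None,
    criteria: list[str] | None = None,
) -> list[EIResult]:
    """One :class:`EIResult` per group x criterion.

    Percent differences are taken against the reference group on
    one-decimal-rounded ratios; Poisson Wald tests compare each
    non-reference group with the reference, flagged significant at the
    Bonferroni-adjusted per-test level.
    """
    config = config or AnalysisConfig()
    ref = config.reference_group
    criteria = criteria if criteria is not None else counts.criteria
    results: list[EIResult] = []
    have_ref = ref in counts.groups
    for crit in criteria:
        col = counts.eligible[crit]
        if have_ref:
            ref_e = col[ref]
            ref_i = counts.incident_cases_6yr[ref]
            ref_rounded = _round_half_away(ei_ratio(ref_e, ref_i))
        for group in counts.groups + ([OVERALL] if OVERALL in counts.n_total else []):
            e = col[group]
            i = counts.incident_cases_6yr[group]
            ratio = ei_ratio(e, i)
            rounded = _round_half_away(ratio)
            if have_ref and group not in (ref, OVERALL):
                pct = percent_difference(rounded, ref_rounded)
                rr, z, p = poisson_compare(ref_e, ref_i, e, i)
                sig = p < config.per_test_alpha
            elif have_ref and group == ref:
                pct, rr, z, p, sig = 0.0, 1.0, 0.0, 1.0, False
            else:
                pct = rr = z = p = sig = None
            results.append(
                EIResult(
                    group=group,
                    criterion=crit,
                    eligible=e,
                    incident_cases=i,
                    ei_ratio=ratio,
                    ei_ratio_rounded=rounded,
                    percent_difference_vs_reference=pct,
                    rate_ratio=rr,
                    wald_z=z,
                    p_value=p,
                    significant_after_bonferroni=sig,
                )
            )
    return results


def performance_table(
    cohort: pd.DataFrame,
    eligibility_masks: dict[str, np.ndarray],
) -> list[PerformanceResult]:
    """Screening performance per criterion, overall and per race."""
    race = cohort["race_ethnicity"].to_numpy()
    outcome = cohort["lung_cancer_6yr"].to_numpy(dtype=bool)
    results = []
    groups = [OVERALL] + sorted(pd.unique(race))
    for crit, mask in eligibility_masks.items():
        mask = np.asarray(mask, dtype=bool)
        for group in groups:
            sel = np.ones(len(cohort), dtype=bool) if group == OVERALL else race == group
            m, y = mask[sel], outcome[sel]
            results.append(
                screening_performance(
                    eligible_cases=int((m & y).sum()),
                    total_cases=int(y.sum()),
                    eligible_noncases=int((m & ~y).sum()),
                    total_noncases=int((~y).sum()),
                    eligible_total=int(m.sum()),
                    group=group,
                    criterion=crit,
                )
            )
    return results


def ei_results_frame(results: list[EIResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def performance_frame(results: list[PerformanceResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
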