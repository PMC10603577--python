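"""Race-stratified predictive-performance metrics.

Discrimination is the AUC in its rank-statistic form (probability that a
random event outranks a random non-event, ties counted half), with a
seeded stratified-bootstrap confidence interval.  Calibration partitions
records into risk-quantile bins (deciles by default) and reports each
bin's mean predicted risk against its observed event proportion; the
calibration slope is the OLS slope of observed on predicted across bins
(1 under perfect calibration, > 1 when the model underestimates risk).
Predictive accuracy is the Brier score, the mean squared difference
between predicted probability and the 0/1 outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ValidationReport:
    group: str
    n: int
    events: int
    auc: float
    auc_ci: tuple[float, float]
    brier: float
    calibration_deciles: pd.DataFrame  # columns: mean_predicted, observed, n
    calibration_slope: float


def _check_scores(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-d and aligned")
    return s, y


def auc(scores, outcomes) -> float:
    """Rank-statistic AUC with the ties-count-half convention."""
    s, y = _check_scores(scores, outcomes)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("undefined AUC: need at least one event and one non-event")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_bootstrap_ci(
    scores, outcomes, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling events and non-events separately."""
    s, y = _check_scores(scores, outcomes)
    rng = np.random.default_rng(seed)
    ev, nev = s[y], s[~y]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        eb = rng.choice(ev, size=ev.size, replace=True)
        nb = rng.choice(nev, size=nev.size, replace=True)
        ranks = rankdata(np.concatenate([eb, nb]))
        u = ranks[: eb.size].sum() - eb.size * (eb.size + 1) / 2.0
        stats[b] = u / (eb.size * nb.size)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def brier(scores, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    s, y = _check_scores(scores, outcomes)
    if s.size == 0:
        raise ValueError("brier score of an empty vector")
    return float(np.mean((s - y.astype(float)) ** 2))


def calibration(scores, outcomes, bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Risk-quantile calibration table and OLS calibration slope.

    Records are ordered by predicted risk (stable sort, so ties are broken
    by record order) and split into ``bins`` near-equal bins — the
    inverse-ECDF quantile convention.  When there are fewer distinct
    scores than bins the bin count is reduced with a warning.

    Returns the per-bin table (mean_predicted, observed, n) and the slope
    of the least-squares line of observed proportions on mean predictions.
    """
    s, y = _check_scores(scores, outcomes)
    if s.size < bins:
        raise ValueError(f"need at least {bins} records for {bins} bins")
    distinct = np.unique(s).size
    if distinct < bins:
        warnings.warn(
            f"only {distinct} distinct scores for {bins} bins; merging bins"
        )
        bins = distinct
    order = np.argsort(s, kind="stable")
    rows = []
    for chunk in np.array_split(order, bins):
        rows.append(
            {
                "mean_predicted": float(s[chunk].mean()),
                "observed": float(y[chunk].mean()),
                "n": int(chunk.size),
            }
        )
    table = pd.DataFrame(rows)
    slope = float(
        np.polyfit(table["mean_predicted"], table["observed"], deg=1)[0]
    )
    return table, slope


def validation_report(
    scores,
    outcomes,
    group: str = "overall",
    bins: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
) -> ValidationReport:
    """All three metrics for one group of records."""
    s, y = _check_scores(scores, outcomes)
    table, slope = calibration(s, y, bins=bins)
    return ValidationReport(
        group=group,
        n=int(s.size),
        events=int(y.sum()),
        auc=auc(s, y),
        auc_ci=auc_bootstrap_ci(s, y, n_boot=n_boot, seed=seed),
        brier=brier(s, y),
        calibration_deciles=table,
        calibration_slope=slope,
    )


def grouped_validation(
    cohort: pd.DataFrame,
    risks,
    bins: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
    include_overall: bool = True,
) -> list[ValidationReport]:
    """Per-race validation reports (plus an overall report)."""
    risks = np.asarray(risks, dtype=float)
    y = cohort["lung_cancer_6yr"].to_numpy(dtype=bool)
    race = cohort["race_ethnicity"].to_numpy()
    reports = []
    if include_overall:
        reports.append(
            validation_report(risks, y, group="overall", bins=bins, n_boot=n_boot, seed=seed)
        )
    for g in sorted(pd.unique(race)):
        sel = race == g
        reports.append(
            validation_report(
                risks[sel], y[sel], group=g, bins=bins, n_boot=n_boot, seed=seed
            )
        )
    return reports
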