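"""Race/ethnicity recalibration of a fixed risk model, plus the
cross-validation harness.

The recalibration keeps every non-race coefficient of the base model
frozen and re-estimates only the race-related parameters on a target
cohort: with ``offset`` the base model's full linear predictor, the
working model is

    logit P(case) = offset + d0 + sum_r d_r * 1[race = r]

with the reference race fixed at ``d_r = 0``, so ``d_r`` is the shift of
group r's race coefficient away from its base value and the updated model
carries ``base + d_r``.  A cohort actually generated by the base model
recovers deltas near zero.  The intercept shift ``d0`` is included so
calibration can move for the reference group as well.  The
maximum-likelihood fit uses iteratively reweighted least squares (exact
Newton) on the small (1 + R - 1)-dimensional problem, with no
regularisation.

A race category exhibiting separation on the fitting data (zero events or
all events) cannot be estimated: it is flagged, its estimate reported as
NaN, and the updated model falls back to the base coefficient for that
category; the run is not fatal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .risk_models import CoefficientSet, linear_predictor, logistic

logger = logging.getLogger(__name__)

GRADIENT_TOL = 1e-8
MAX_ITER = 100


@dataclass
class RecalibrationResult:
    updated_model: CoefficientSet
    estimates: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    n_iterations: int
    converged: bool
    log_likelihood: float
    separated: tuple[str, ...] = ()


def _base_offset(cohort: pd.DataFrame, model: CoefficientSet) -> np.ndarray:
    """The frozen part of the working model: the base linear predictor."""
    return linear_predictor(cohort, model)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1 + exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls_offset_logit(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Newton/IRLS MLE of logit P(y) = offset + X beta.

    Newton steps are damped by halving whenever a full step would decrease
    the log-likelihood (the likelihood is concave, so damped Newton from
    zero converges whenever the MLE exists).

    Returns (beta, SE, n_iter, converged, loglik).
    """
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    ll = _bernoulli_loglik(y, offset + X @ beta)
    for it in range(1, MAX_ITER + 1):
        eta = offset + X @ beta
        p = logistic(eta)
        grad = X.T @ (y - p)
        if np.linalg.norm(grad) < GRADIENT_TOL:
            converged = True
            break
        W = np.maximum(p * (1.0 - p), 1e-12)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(30):
            ll_new = _bernoulli_loglik(y, offset + X @ (beta + scale * step))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = _bernoulli_loglik(y, offset + X @ beta)
    eta = offset + X @ beta
    p = logistic(eta)
    W = np.maximum(p * (1.0 - p), 1e-12)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, np.sqrt(np.diag(cov)), it, converged, _bernoulli_loglik(y, eta)


def fit_race_recalibration(
    cohort: pd.DataFrame,
    base_model: CoefficientSet,
    reference_race: str | None = None,
) -> RecalibrationResult:
    """Re-estimate race-related parameters on a cohort, all else frozen.

    The returned model differs from ``base_model`` only in its intercept
    (shifted by the fitted ``d0``) and its race coefficients (the fitted
    ``d_r``, 0 for the reference).  Categories absent from the cohort or
    separated keep their base coefficients.
    """
    if reference_race is None:
        reference_race = base_model.reference_race
    races_present = [r for r in pd.unique(cohort["race_ethnicity"])]
    if len(races_present) < 2:
        raise ValueError("recalibration needs at least 2 race categories")
    y = cohort["lung_cancer_6yr"].to_numpy(dtype=float)
    race = cohort["race_ethnicity"].to_numpy()

    fit_races, separated = [], []
    for r in sorted(races_present):
        if r == reference_race:
            continue
        events = y[race == r].sum()
        if events == 0 or events == (race == r).sum():
            separated.append(r)
            logger.warning("separation in race category %r: estimate undefined", r)
        else:
            fit_races.append(r)
    if y[race == reference_race].sum() == 0:
        warnings.warn(f"reference race {reference_race!r} has no events")

    keep = ~np.isin(race, separated)
    offset = _base_offset(cohort, base_model)[keep]
    yk, racek = y[keep], race[keep]
    X = np.column_stack(
        [np.ones(keep.sum())] + [(racek == r).astype(float) for r in fit_races]
    )
    beta, se, n_iter, converged, loglik = _irls_offset_logit(X, yk, offset)

    estimates: dict[str, tuple[float, float]] = {"intercept_shift": (beta[0], se[0])}
    new_race = {reference_race: 0.0}
    for j, r in enumerate(fit_races, start=1):
        estimates[r] = (beta[j], se[j])
        new_race[r] = base_model.race_coefficient(r) + float(beta[j])
    for r in separated:
        estimates[r] = (float("nan"), float("nan"))
        new_race[r] = base_model.race_coefficient(r)
    for r in base_model.race_coefficients:
        new_race.setdefault(r, base_model.race_coefficient(r))

    updated = base_model.with_race_update(
        intercept_shift=float(beta[0]),
        race_coefficients=new_race,
        suffix="-Update",
    )
    return RecalibrationResult(
        updated_model=updated,
        estimates=estimates,
        n_iterations=n_iter,
        converged=converged,
        log_likelihood=loglik,
        separated=tuple(separated),
    )


def crossfit_predictions(
    cohort: pd.DataFrame,
    base_model: CoefficientSet,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold recalibrated risk for every record.

    The cohort is partitioned into ``folds`` folds stratified by outcome
    (falling back to unstratified folds, with a warning, when a class has
    fewer members than folds, e.g. leave-one-out); each record is scored by
    the recalibration fitted on the other folds.  Deterministic given
    ``seed``; every record is scored exactly once.

    Returns a frame with columns id, fold, linear_predictor, risk aligned
    with the cohort's row order.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = cohort["lung_cancer_6yr"].to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("cross-validation needs both events and non-events")
    if min(np.bincount(y)) >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            "a class has fewer members than folds; using unstratified folds"
        )
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)

    lp_out = np.full(len(cohort), np.nan)
    fold_id = np.full(len(cohort), -1, dtype=int)
    for k, (train, test) in enumerate(splitter.split(np.zeros(len(y)), y)):
        if y[train].sum() == 0:
            raise ValueError(f"training folds for fold {k} contain no events")
        fit = fit_race_recalibration(cohort.iloc[train], base_model)
        lp_out[test] = linear_predictor(cohort.iloc[test], fit.updated_model)
        fold_id[test] = k
    assert not np.isnan(lp_out).any()
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "fold": fold_id,
            "linear_predictor": lp_out,
            "risk": logistic(lp_out),
        }
    )
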