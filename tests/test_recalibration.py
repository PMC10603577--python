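import math

import numpy as np
import pandas as pd
import pytest

import lungscreen as ls
from lungscreen.data_model import records_to_cohort
from lungscreen.recalibration import crossfit_predictions, fit_race_recalibration
from lungscreen.risk_models import ModelTerm, linear_predictor, logistic
from lungscreen.synthetic_cohort import SyntheticSpec, generate_cohort
from tests.conftest import toy_record


def _loglik(cohort, model):
    p = np.clip(logistic(linear_predictor(cohort, model)), 1e-12, 1 - 1e-12)
    y = cohort["lung_cancer_6yr"].to_numpy(float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _constant_offset_model(intercept, other_coef=0.3):
    """Covariate-free base model: offset is constant within each race group
    (intercept for white, intercept + other_coef for african_american)."""
    return ls.CoefficientSet(
        model_name="const",
        intercept=intercept,
        terms=(),
        race_coefficients={"white": 0.0, "african_american": other_coef},
    )


def _two_race_cohort(n_ref, k_ref, n_other, k_other):
    """white: k_ref events of n_ref; african_american: k_other of n_other."""
    records = []
    for i in range(n_ref):
        records.append(
            toy_record(id=f"w{i}", race_ethnicity="white", lung_cancer_6yr=i < k_ref)
        )
    for i in range(n_other):
        records.append(
            toy_record(
                id=f"a{i}", race_ethnicity="african_american", lung_cancer_6yr=i < k_other
            )
        )
    return records_to_cohort(records)


class TestFitRaceRecalibration:
    def test_two_by_two_closed_form(self):
        """With a constant offset, the race delta is exactly the
        log-odds-ratio of the 2x2 (race x outcome) table."""
        cohort = _two_race_cohort(200, 20, 150, 30)
        base = _constant_offset_model(-1.5, other_coef=0.3)
        fit = fit_race_recalibration(cohort, base, reference_race="white")
        log_or = math.log((30 / 120) / (20 / 180))
        d_aa, se = fit.estimates["african_american"]
        assert fit.converged
        # the delta sits on top of the base race coefficient, so the fitted
        # group log-odds difference (base + delta) is exactly the 2x2 logOR
        assert 0.3 + d_aa == pytest.approx(log_or, abs=1e-8)
        # intercept shift moves the constant to the reference log-odds
        d0, _ = fit.estimates["intercept_shift"]
        assert base.intercept + d0 == pytest.approx(math.log(20 / 180), abs=1e-8)
        # SE of a log-odds-ratio: sqrt of summed reciprocal cell counts
        assert se == pytest.approx(math.sqrt(1 / 30 + 1 / 120 + 1 / 20 + 1 / 180), rel=1e-6)

    def test_null_recovery(self, cohort_100k_null, true_model_100k_null):
        """Refit on data generated by the base model itself: every delta
        within 3 standard errors of zero."""
        fit = fit_race_recalibration(cohort_100k_null, true_model_100k_null)
        assert fit.converged
        for name, (est, se) in fit.estimates.items():
            assert abs(est) < 3 * se, name

    def test_injected_offset_recovery(self, original_model):
        """Race shifts injected into the generating model are recovered
        within +/-0.15 at n = 100k and ~1.4% prevalence."""
        injected = {"african_american": 0.5, "latino": -0.4}
        rc = dict(original_model.race_coefficients)
        for r, d in injected.items():
            rc[r] += d
        gen = ls.CoefficientSet(
            original_model.model_name + "-inj",
            original_model.intercept,
            original_model.terms,
            rc,
        )
        cohort = generate_cohort(SyntheticSpec(n=100_000, seed=11, true_model=gen))
        base = original_model.with_race_update(
            cohort.attrs["true_intercept_offset"],
            original_model.race_coefficients,
            "-b",
        )
        fit = fit_race_recalibration(cohort, base)
        for r, d in injected.items():
            assert fit.estimates[r][0] == pytest.approx(d, abs=0.15)
        for r in ("japanese_american", "nhpi"):
            assert fit.estimates[r][0] == pytest.approx(0.0, abs=0.15)

    def test_updated_model_differs_only_in_race_parameters(
        self, cohort_20k, original_model
    ):
        fit = fit_race_recalibration(cohort_20k, original_model)
        assert fit.updated_model.terms == original_model.terms
        assert fit.updated_model.intercept != original_model.intercept

    def test_loglik_dominates_base_model(self, cohort_20k, original_model):
        fit = fit_race_recalibration(cohort_20k, original_model)
        assert fit.log_likelihood >= _loglik(cohort_20k, original_model)
        assert fit.log_likelihood == pytest.approx(
            _loglik(cohort_20k, fit.updated_model), abs=1e-6
        )

    def test_mean_predicted_matches_event_rate(self, cohort_20k, original_model):
        """Self-consistency: the recalibrated mean risk tracks the cohort
        event rate within 5% relative."""
        fit = fit_race_recalibration(cohort_20k, original_model)
        mean_risk = logistic(linear_predictor(cohort_20k, fit.updated_model)).mean()
        rate = cohort_20k["lung_cancer_6yr"].mean()
        assert mean_risk == pytest.approx(rate, rel=0.05)

    def test_agrees_with_statsmodels_offset_fit(self, original_model):
        import statsmodels.api as sm

        cohort = generate_cohort(SyntheticSpec(n=5000, seed=13, target_incidence=0.05))
        fit = fit_race_recalibration(cohort, original_model)
        offset = linear_predictor(cohort, original_model)
        race = cohort["race_ethnicity"].to_numpy()
        others = [r for r in sorted(set(race)) if r != "white"]
        X = np.column_stack(
            [np.ones(len(cohort))] + [(race == r).astype(float) for r in others]
        )
        y = cohort["lung_cancer_6yr"].to_numpy(float)
        sm_fit = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit()
        ours = [fit.estimates["intercept_shift"][0]] + [
            fit.estimates[r][0] for r in others
        ]
        assert np.allclose(ours, sm_fit.params, atol=1e-6)
        ses = [fit.estimates["intercept_shift"][1]] + [fit.estimates[r][1] for r in others]
        assert np.allclose(ses, sm_fit.bse, atol=1e-6)

    def test_separation_flagged_not_fatal(self):
        cohort = _two_race_cohort(100, 10, 50, 0)  # no events among african_american
        base = _constant_offset_model(-2.0)
        fit = fit_race_recalibration(cohort, base, reference_race="white")
        assert "african_american" in fit.separated
        assert math.isnan(fit.estimates["african_american"][0])
        assert fit.converged

    def test_single_race_rejected(self):
        records = [toy_record(id=f"r{i}", lung_cancer_6yr=i < 3) for i in range(20)]
        with pytest.raises(ValueError, match="2 race categories"):
            fit_race_recalibration(records_to_cohort(records), _constant_offset_model(-2.0))


class TestCrossfitPredictions:
    def test_fold_sizes_balanced_within_strata(self, original_model):
        cohort = generate_cohort(SyntheticSpec(n=1000, seed=17, target_incidence=0.05))
        out = crossfit_predictions(cohort, original_model, folds=10, seed=1)
        y = cohort["lung_cancer_6yr"].to_numpy()
        for stratum in (True, False):
            sizes = out.loc[y == stratum, "fold"].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_every_record_scored_once(self, original_model):
        cohort = generate_cohort(SyntheticSpec(n=500, seed=19, target_incidence=0.05))
        out = crossfit_predictions(cohort, original_model, folds=5, seed=0)
        assert len(out) == len(cohort)
        assert out["risk"].notna().all()
        assert (out["fold"] >= 0).all()

    def test_leave_one_out_runs(self):
        records = [
            toy_record(
                id=f"r{i}",
                race_ethnicity="white" if i % 2 else "african_american",
                lung_cancer_6yr=i < 10,
            )
            for i in range(50)
        ]
        cohort = records_to_cohort(records)
        with pytest.warns(UserWarning, match="unstratified"):
            out = crossfit_predictions(cohort, _constant_offset_model(-2.0), folds=50, seed=2)
        assert len(out) == 50 and out["risk"].notna().all()

    def test_same_seed_identical_scores(self, original_model):
        cohort = generate_cohort(SyntheticSpec(n=800, seed=23, target_incidence=0.05))
        a = crossfit_predictions(cohort, original_model, folds=5, seed=9)
        b = crossfit_predictions(cohort, original_model, folds=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_fold_matches_independent_replicate(self, original_model):
        """CV metrics agree with metrics from a fit applied to an
        independent replicate cohort (within simulation noise)."""
        from lungscreen.validation_metrics import auc

        train = generate_cohort(SyntheticSpec(n=30_000, seed=29))
        replicate = generate_cohort(SyntheticSpec(n=30_000, seed=31))
        oof = crossfit_predictions(train, original_model, folds=10, seed=3)
        auc_cv = auc(oof["risk"], train["lung_cancer_6yr"])
        fit = fit_race_recalibration(train, original_model)
        rep_risk = logistic(linear_predictor(replicate, fit.updated_model))
        auc_rep = auc(rep_risk, replicate["lung_cancer_6yr"])
        assert auc_cv == pytest.approx(auc_rep, abs=0.03)
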