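import math

import numpy as np
import pytest

import lungscreen as ls
from lungscreen.risk_models import (
    CoefficientError,
    ModelTerm,
    linear_predictor,
    logistic,
    logit,
    map_race3l_cohort,
    save_coefficients,
)
from lungscreen.data_model import records_to_cohort
from tests.conftest import toy_record


class TestLoadCoefficients:
    def test_packaged_original_shape(self, original_model):
        assert len(original_model.terms) == 10  # + race term = 11 predictors
        assert original_model.reference_race == "white"
        assert set(original_model.race_coefficients) == {
            "white", "african_american", "japanese_american", "latino", "nhpi",
        }

    def test_two_zero_races_ambiguous(self, tmp_path):
        model = ls.load_original_model()
        doc_path = tmp_path / "bad.yaml"
        save_coefficients(model, doc_path)
        text = doc_path.read_text().replace("african_american: 0.3944778", "african_american: 0.0")
        doc_path.write_text(text)
        with pytest.raises(CoefficientError, match="ambiguous reference"):
            ls.load_coefficients(doc_path)

    def test_toy_terms_preserved_in_order(self, tmp_path):
        toy = ls.CoefficientSet(
            model_name="toy",
            intercept=-1.0,
            terms=(
                ModelTerm(variable="age", coefficient=0.5, transformation="center", center=60),
                ModelTerm(variable="bmi", coefficient=-0.1),
            ),
            race_coefficients={"white": 0.0, "latino": -0.2},
        )
        path = tmp_path / "toy.yaml"
        save_coefficients(toy, path)
        back = ls.load_coefficients(path)
        assert [t.variable for t in back.terms] == ["age", "bmi"]
        assert back == toy

    def test_unknown_transformation_fatal(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "schema_version: 1\nmodel_name: x\nintercept: 0\n"
            "terms:\n  - {variable: age, transformation: cube, coefficient: 1}\n"
            "race_coefficients: {white: 0.0}\n"
        )
        with pytest.raises(CoefficientError, match="transformation"):
            ls.load_coefficients(path)

    def test_missing_schema_version_fatal(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("model_name: x\nintercept: 0\nterms: []\nrace_coefficients: {white: 0.0}\n")
        with pytest.raises(CoefficientError, match="schema_version"):
            ls.load_coefficients(path)


class TestComputeRisk:
    def test_zero_term_model_closed_form(self):
        toy = ls.CoefficientSet(
            model_name="toy", intercept=-4.0,
            terms=(ModelTerm(variable="age", coefficient=0.0),),
            race_coefficients={"white": 0.0},
        )
        score = ls.compute_risk(toy_record(), toy)
        assert score.risk == pytest.approx(1.0 / (1.0 + math.exp(4.0)), abs=1e-12)

    def test_record_at_centers_gives_logistic_intercept(self, original_model):
        rec = toy_record(
            race_ethnicity="white", age=62, education=4, bmi=27.0,
            copd_emphysema=False, personal_cancer_history=False,
            family_history_lung_cancer=False, smoking_status="former",
            intensity=10.0 / 0.4021541613,  # (x/10)^-1 equals the transform center
            duration=27.0, quit_years=10.0,
        )
        score = ls.compute_risk(rec, original_model)
        assert score.linear_predictor == pytest.approx(original_model.intercept, abs=1e-10)

    def test_fixed_record_matches_hand_arithmetic(self, original_model):
        rec = toy_record(
            race_ethnicity="nhpi", age=66, education=3, bmi=24.5,
            copd_emphysema=True, personal_cancer_history=False,
            family_history_lung_cancer=True, smoking_status="current",
            intensity=15.0, duration=40.0, quit_years=0.0,
        )
        # independent arithmetic, written out term by term
        lp = (
            -4.532506
            + 0.0778868 * (66 - 62)
            + -0.0812744 * (3 - 4)
            + -0.0274194 * (24.5 - 27)
            + 0.3553063 * 1
            + 0.4589971 * 0
            + 0.587185 * 1
            + 0.2597431 * 1
            + -1.822606 * ((15.0 / 10.0) ** -1 - 0.4021541613)
            + 0.0317321 * (40 - 27)
            + -0.0308572 * (0 - 10)
            + 1.027152
        )
        score = ls.compute_risk(rec, original_model)
        assert score.linear_predictor == pytest.approx(lp, abs=1e-10)
        assert score.risk == pytest.approx(1.0 / (1.0 + math.exp(-lp)), abs=1e-10)

    def test_nonpositive_intensity_fatal(self, original_model):
        rec = toy_record(intensity=0.0)
        with pytest.raises(CoefficientError, match="intensity"):
            ls.compute_risk(rec, original_model)

    def test_vectorised_scoring_matches_scalar(self, original_model):
        records = [
            toy_record(id=f"r{i}", age=50 + i, race_ethnicity=race, intensity=5 + i)
            for i, race in enumerate(ls.data_model.RACE_CATEGORIES)
        ]
        cohort = records_to_cohort(records)
        scored = ls.score_cohort(cohort, original_model)
        for rec, (_, row) in zip(records, scored.iterrows()):
            assert row["risk"] == pytest.approx(ls.compute_risk(rec, original_model).risk)

    def test_risk_monotone_in_duration(self, original_model):
        risks = [
            ls.compute_risk(toy_record(duration=d, pack_years=d), original_model).risk
            for d in (10, 20, 30, 40)
        ]
        assert risks == sorted(risks)

    def test_logistic_logit_round_trip(self):
        # exact where p is well conditioned; in the upper tail 1 - p loses
        # relative precision in float64, bounding accuracy near 1e-8
        lp = np.linspace(-20, 5, 101)
        assert np.max(np.abs(logit(logistic(lp)) - lp)) < 1e-12
        lp = np.linspace(-20, 20, 101)
        assert np.max(np.abs(logit(logistic(lp)) - lp)) < 1e-6

    def test_probability_round_trip_exact(self):
        p = np.linspace(1e-9, 1 - 1e-9, 101)
        assert np.max(np.abs(logistic(logit(p)) - p)) < 1e-12


class TestRace3L:
    @pytest.mark.parametrize(
        "race,expected",
        [
            ("nhpi", "white"),
            ("japanese_american", "white"),
            ("latino", "white"),
            ("african_american", "african_american"),
            ("white", "white"),
        ],
    )
    def test_category_mapping(self, race, expected):
        rec = toy_record(race_ethnicity=race)
        assert ls.map_race3l(rec).race_ethnicity == expected

    def test_merged_file_equals_mapped_original_scoring(self, original_model):
        """Scoring with the merged-race file equals mapping categories first
        and scoring with a file whose race map only has the 3 levels."""
        race3l = ls.load_race3l_model()
        for race in ls.data_model.RACE_CATEGORIES:
            rec = toy_record(race_ethnicity=race)
            direct = ls.compute_risk(rec, race3l)
            mapped = ls.compute_risk(ls.map_race3l(rec), race3l)
            assert direct.risk == pytest.approx(mapped.risk, abs=1e-15)

    def test_cohort_mapping(self, cohort_20k):
        mapped = map_race3l_cohort(cohort_20k)
        assert set(mapped["race_ethnicity"].unique()) <= {"white", "african_american"}
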