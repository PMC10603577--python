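"""Score one participant's 6-year lung cancer risk with the packaged model.

The model is a logistic absolute-risk model for ever-smokers: age,
education, BMI, COPD/emphysema, personal cancer history, family history of
lung cancer, smoking status/intensity/duration/quit-years, and
race/ethnicity enter a linear predictor; risk = logistic(lp).
"""

from lungscreen import ParticipantRecord, compute_risk, load_original_model

model = load_original_model()

participant = ParticipantRecord(
    id="example", race_ethnicity="african_american", age=64, sex="female",
    education=2, bmi=27.5, copd_emphysema=True, personal_cancer_history=False,
    family_history_lung_cancer=True, smoking_status="former",
    intensity=20.0, duration=38.0, quit_years=4.0, pack_years=38.0,
    lung_cancer_6yr=False,
)

score = compute_risk(participant, model)
print(f"linear predictor : {score.linear_predictor:.4f}")
print(f"6-year risk      : {score.risk:.4f}")
print()
print("A risk of", round(score.risk, 3), "means this smoking history carries a")
print("predicted", f"{100 * score.risk:.1f}%", "chance of incident lung cancer within 6")
print("years; at the 1.3% risk-based cutoff this participant would be")
print("screening-eligible." if score.risk >= 0.013 else "screening-ineligible.")
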