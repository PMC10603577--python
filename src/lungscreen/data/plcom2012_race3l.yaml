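# Three-level-race variant of PLCOm2012: the Asian, Hispanic and Native
# Hawaiian/Other Pacific Islander categories are merged into the White
# reference; the non-race terms are those of the original model.
schema_version: 1
model_name: PLCOm2012-Race3L
intercept: -4.532506
terms:
  - {variable: age, transformation: center, center: 62, coefficient: 0.0778868}
  - {variable: education, transformation: center, center: 4, coefficient: -0.0812744}
  - {variable: bmi, transformation: center, center: 27, coefficient: -0.0274194}
  - {variable: copd_emphysema, transformation: identity, coefficient: 0.3553063}
  - {variable: personal_cancer_history, transformation: identity, coefficient: 0.4589971}
  - {variable: family_history_lung_cancer, transformation: identity, coefficient: 0.587185}
  - {variable: smoking_status, transformation: indicator, level: current, coefficient: 0.2597431}
  - {variable: intensity, transformation: reciprocal_scaled, scale: 10, center: 0.4021541613, coefficient: -1.822606}
  - {variable: duration, transformation: center, center: 27, coefficient: 0.0317321}
  - {variable: quit_years, transformation: center, center: 10, coefficient: -0.0308572}
race_coefficients:
  white: 0.0
  african_american: 0.3944778
race_merge:
  japanese_american: white
  latino: white
  nhpi: white
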