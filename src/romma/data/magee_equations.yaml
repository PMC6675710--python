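# Modified Magee equation coefficients.
#
# Transcribed from the public Magee-equation calculator maintained by the
# University of Pittsburgh Medical Center Department of Pathology:
#   https://path.upmc.edu/onlineTools/mageeequations.html
# Transcription date: 2026-09-20.
#
# Each equation predicts the Oncotype DX recurrence score from a different
# subset of routine pathology variables. ER/PR enter as H-scores (0-300),
# Ki-67 as a percentage, tumor size in cm. The her2_term coefficient of 1.0
# multiplies the status-mapped her2_term_values entry for the case's
# resolved HER-2 status.
version: "1.0"
equations:
  - equation_id: eq1
    intercept: 15.31385
    coefficients:
      nottingham_score: 1.4055
      er_h_score: -0.01924
      pr_h_score: -0.02925
      her2_term: 1.0
      tumor_size_cm: 0.78677
      ki67_pct: 0.13269
    her2_term_values:
      negative: 0.0
      equivocal: 0.77681
      positive: 11.58134
    required_predictors:
      - nottingham_score
      - er_h_score
      - pr_h_score
      - her2_term
      - tumor_size_cm
      - ki67_pct
  - equation_id: eq2
    intercept: 18.8042
    coefficients:
      nottingham_score: 2.34123
      er_h_score: -0.03749
      pr_h_score: -0.03065
      her2_term: 1.0
      tumor_size_cm: 0.04267
    her2_term_values:
      negative: 0.0
      equivocal: 1.82921
      positive: 11.51378
    required_predictors:
      - nottingham_score
      - er_h_score
      - pr_h_score
      - her2_term
      - tumor_size_cm
  - equation_id: eq3
    intercept: 24.30812
    coefficients:
      er_h_score: -0.02177
      pr_h_score: -0.02884
      her2_term: 1.0
      ki67_pct: 0.18649
    her2_term_values:
      negative: 0.0
      equivocal: 1.46495
      positive: 12.75525
    required_predictors:
      - er_h_score
      - pr_h_score
      - her2_term
      - ki67_pct
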