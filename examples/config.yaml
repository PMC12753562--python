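# Demo study configuration for `tmcohort run --config examples/config.yaml`.
# Omitted fields fall back to the package defaults (see tmcohort.config);
# the values below define a small end-to-end run that finishes in a couple
# of minutes on one CPU.

simulation:
  n_patients: 5000          # claims universe size
  study_start: "2017-12-01"
  study_end: "2023-07-31"
  drug_launch_date: "2018-06-01"
  true_log_hr: 0.0          # null exposure effect on the outcome hazard
  baseline_hazard: 3.6e-05  # outcome events per person-day (~1.3 / 100 PY)
  ever_user_fraction: 0.10  # study-drug uptake probability at reference covariates
  inpatient_fraction: 0.30
  seed: 20180601
  missing_spec:
    target: 0.8             # MAR-deleted fraction of BMI / smoking
    beta_age_per_decade: 0.25
    beta_female: 0.10
    beta_diabetes: -0.40

design:
  cutoff_date: "2018-06-01" # first eligible dyslipidemia diagnosis on/after
  baseline_days: 180
  match_ratio: 5
  min_age: 20
  gap_grace_days: [0, 30, 90, 180]
  n_imputations: 5          # 20 in the full design; 5 keeps the demo quick
  seed: 20180601
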