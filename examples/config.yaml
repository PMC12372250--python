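# Full synthetic run at study scale: 935 patients, six interventions,
# single-pass recalibration, published risk coefficients.
seed: 1
synthetic:
  n_patients: 935
  n_peptides: 1500
  n_classifier_peptides: 273
  missing_rate: 0.25
  score_location: 0.565
  score_scale: 0.30
k_interventions: 6
trial_effects:        # observed % improvement in time to MAKE, per trial
  ARB: 20.0
  Exercise: 15.0
  GLP1RA: 25.0
  MRA: 25.0
  OliveOil: 10.0
  SGLT2i: 35.0
calibration_mode: single_pass
risk_source: published_constants
days_per_year: 365.25
output_dir: out
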