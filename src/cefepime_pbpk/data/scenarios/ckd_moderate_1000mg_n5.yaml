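# Moderate renal impairment (CrCL 31-60 mL/min), 1000 mg over 30 min (n=5).
# Longer horizon: the drug persists far beyond a healthy dosing interval.
name: ckd_moderate_1000mg_n5
description: Moderate CKD patients, 1000 mg IV over 30 min
population:
  n_subjects: 5
  age_range: [31.4, 60.6]
  weight_range: [57.5, 74.4]
  n_females: 0
  disease: moderate_ckd
regimen:
  dose_mg: 1000
  infusion_duration_min: 30
simulation:
  horizon_h: 48.0
  dt_h: 0.05
  seed: 108
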