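# Severe renal impairment (CrCL 11-30 mL/min), 1000 mg over 30 min (n=5).
name: ckd_severe_1000mg_n5
description: Severe CKD patients, 1000 mg IV over 30 min
population:
  n_subjects: 5
  age_range: [27.4, 62.6]
  weight_range: [64.6, 101.4]
  n_females: 0
  disease: severe_ckd
regimen:
  dose_mg: 1000
  infusion_duration_min: 30
simulation:
  horizon_h: 48.0
  dt_h: 0.05
  seed: 109
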