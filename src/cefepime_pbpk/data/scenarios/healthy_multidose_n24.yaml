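# Healthy adults, dose-escalation study (62.5-2000 mg, 30 min infusions).
# The 1000 mg arm is encoded; other arms differ only in dose_mg.
name: healthy_multidose_n24
description: Healthy volunteers, dose escalation, 1000 mg arm
population:
  n_subjects: 24
  age_range: [28.5, 33.5]
  weight_range: [84.6, 93.2]
  n_females: 0
  disease: healthy
regimen:
  dose_mg: 1000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 102
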