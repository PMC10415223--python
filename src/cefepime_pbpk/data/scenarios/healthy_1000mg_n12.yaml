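# Healthy adults, single 1000 mg dose as a 30 min IV infusion (n=12, 6 F).
name: healthy_1000mg_n12
description: Healthy volunteers, 1000 mg IV over 30 min
population:
  n_subjects: 12
  age_range: [25.2, 27.8]
  weight_range: [66.5, 80.3]
  n_females: 6
  disease: healthy
regimen:
  dose_mg: 1000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 101
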