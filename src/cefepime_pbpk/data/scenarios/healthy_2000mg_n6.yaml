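# Healthy adults, single 2000 mg dose over 30 min (n=6).
name: healthy_2000mg_n6
description: Healthy volunteers, 2000 mg IV over 30 min
population:
  n_subjects: 6
  age_range: [23, 43]
  weight_range: [72.2, 110]
  n_females: 0
  disease: healthy
regimen:
  dose_mg: 2000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 104
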