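# Healthy adults across a wide age span, 1000 mg over 30 min (n=48, 24 F).
name: healthy_1000mg_n48
description: Healthy volunteers, 1000 mg IV over 30 min, wide age range
population:
  n_subjects: 48
  age_range: [20, 81]
  weight_range: [54, 86]
  n_females: 24
  disease: healthy
regimen:
  dose_mg: 1000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 106
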