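# Obese adults (BMI > 30), 2000 mg over 30 min (n=10, 5 F).
name: obese_2000mg_n10
description: Obese adults, 2000 mg IV over 30 min
population:
  n_subjects: 10
  age_range: [31, 74]
  weight_range: [106.8, 163.2]
  n_females: 5
  disease: obese
regimen:
  dose_mg: 2000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 110
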