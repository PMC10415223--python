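# Healthy adults, 2000 mg given as short infusions (3, 5, 10 or 15 min);
# the 15 min arm is encoded. Weights were not reported; a typical adult
# male range is assumed.
name: healthy_2000mg_short_infusion_n16
description: Healthy volunteers, 2000 mg IV over 15 min
population:
  n_subjects: 16
  age_range: [21, 38]
  weight_range: [60, 90]
  n_females: 0
  disease: healthy
regimen:
  dose_mg: 2000
  infusion_duration_min: 15
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 103
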