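# Healthy adults, dose-ranging crossover (250-2000 mg); 2000 mg arm encoded.
name: healthy_multidose_n3
description: Healthy volunteers, dose ranging, 2000 mg arm
population:
  n_subjects: 3
  age_range: [20, 44]
  weight_range: [70.6, 79]
  n_females: 0
  disease: healthy
regimen:
  dose_mg: 2000
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 105
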