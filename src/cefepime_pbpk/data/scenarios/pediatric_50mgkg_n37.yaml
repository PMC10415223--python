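# Pediatric patients 2 months - 16.4 years, 50 mg/kg over 30 min (n=37, 16 F).
name: pediatric_50mgkg_n37
description: Pediatric patients, 50 mg/kg IV over 30 min
population:
  n_subjects: 37
  age_range: [0.175, 16.4]
  weight_range: [3.5, 75]
  n_females: 16
  disease: pediatric
regimen:
  dose_mg_per_kg: 50
  infusion_duration_min: 30
simulation:
  horizon_h: 12.0
  dt_h: 0.05
  seed: 107
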