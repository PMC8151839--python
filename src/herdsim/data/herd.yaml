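# Tier 2 (herd/module): breed, reproduction protocols, lactation curves.
herd:
  breed: Holstein
  mature_bw: {mean: 680, sd: 55, lower: 520, upper: 820}
  calf_birth_bw: {mean: 42, sd: 4, lower: 30, upper: 55}
  weaning_day: 56
  weaning_period: 14
  keep_female_calf_rate: 1.0
  stillbirth_probability: 0.06
  female_calf_probability: 0.5
  pre_fresh_period: 30
  dry_off_day: 220
  heifer_repro_cull_age: 700
  cow_repro_cull_dim: 400
  milk_fat_pct: 3.8
  milk_protein_pct: 3.1
  lactation_curve:
    primiparous: {a: 17.5, b: 0.22, c: 0.0030}
    multiparous: {a: 21.5, b: 0.22, c: 0.0034}

reproduction:
  heifer:
    protocol: estrus_detection
    breeding_start: 400
    conception_probability: 0.55
    estrus_detection_probability: 0.65
  cow:
    protocol: estrus_detection
    breeding_start: 60            # voluntary waiting period, DIM
    conception_probability: 0.40
    estrus_detection_probability: 0.60
  estrous_cycle: {mean: 21, sd: 2, lower: 18, upper: 25}
  gestation_length: {mean: 279, sd: 5, lower: 266, upper: 294}
  pregnancy_check_days: [35, 90, 180]
  pregnancy_loss_rate: 0.12
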