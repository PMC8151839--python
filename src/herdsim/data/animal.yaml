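# Tier 3 (animal/detail): growth targets, culling hazards, efficiency draws.
herd:
  calf_target_adg: 0.8
  estimated_lactation_length: 340
  culling:
    low_production: 0.060
    lameness: 0.045
    injury: 0.074
    mastitis: 0.054
    disease: 0.000
    udder: 0.017
    unknown: 0.038

efficiency:
  scenario: Baseline
  sd: 0.06

ration:
  lead_factor: 1.0
  max_milk_reductions: 20
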