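# Tier 1 (farm): simulation window, herd size, output location.
simulation:
  start_date: 2020-01-01
  end_date: 2020-12-30          # 365 simulated days (day index 0..364)
  random_seed: 17
  ration_interval: 3
  output_dir: output

herd:
  target_lactating_cows: 200
  dry_fraction: 0.15
  n_lactating_pens: 3

enteric_model: niu
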