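# Pipeline configuration: a synthetic study corpus with planted signals.
# Swap `synthetic:` for `input_dir: <path>` to analyze a directory of
# quarterly FAERS-format archives instead.
target_drug: pralatrexate
synthetic:
  n_target_reports: 563
  n_background_reports: 20000
  duplicate_fraction: 0.10
  deleted_fraction: 0.02
  tto_scale: 45.74      # Weibull onset scale, days
  tto_shape: 0.63       # Weibull onset shape (<1: early-failure pattern)
  missing_date_fraction: 0.44
  seed: 20090924
signal:
  min_count: 3          # minimum target-report count per tested PT
  bcpnn_draws: 100000
  seed: 20090924
output_dir: pvsignal_out
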