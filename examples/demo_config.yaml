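# Small end-to-end pipeline demo: two synthetic sites, three years each.
# Run with:  hybridevap all --config examples/demo_config.yaml
seed: 3
workdir: pipeline_out

generate:
  n_days: 1095
  n_sites: 2
  noise_sd_mm: 0.05

prepare:
  ept_scaling: none        # synthetic potential transpiration is undistorted
  rain_threshold_mm: 0.5

train:
  hidden: [64, 64, 64]
  max_epochs: 200
  patience: 20

run:
  mode: hybrid
  veg_class: tall
  frac_tall: 1.0
  frac_short: 0.0
  frac_bare: 0.0
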