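# Desk-scale quickstart: synthetic single-channel one-second windows with a
# clearly separable seizure regime, cross-validated in a couple of minutes.
# Run:  seizurekit train docs/quickstart.yaml
dataset:
  preset: tusz
  n_records: 120
  n_channels: 1
  n_samples: 256
  seizure_fraction: 0.5
  gamma_amp: 2.0
  burst_amp: 3.0
  noise_sd: 0.3
features:
  type: dwt
  wavelet: db1
  level: 3
training:
  k_folds: 4
  epochs: 20
  batch_size: 60
output_dir: runs/quickstart
seed: 7
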