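# Mini dual-Key model on the 56x56 synthetic cross-window task.
model:
  embed_dim: 32
  depths: [1, 1]
  heads: [2, 4]
  input_hw: [56, 56]
  num_classes: 2
  variant: DA
train:
  eta: 0.001
  optimizer: adamw
  epochs: 40
  batch_size: 12
  seed: 0
data:
  task: cross_window
  n_samples: 240
  image_hw: [56, 56]
  noise_sd: 0.0
  seed: 0
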