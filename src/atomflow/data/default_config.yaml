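# Default training configuration for the atomflow CLI.
model:
  n_blocks: 4
  ds: 64
  dv: 16
  de: 32
  n_rbf: 16
  rbf_max: 10.0
  time_embedding_dim: 16
  self_conditioning: true
  n_cross: 4
flows:
  loss_weights:
    coords: 1.0
    atom_types: 1.0
    charges: 1.0
    bonds: 1.0
corruption:
  fake_atoms:
    p: 0.3
    offset_sigma: 1.0
  distortion:
    p_distort: 0.2
    t_distort: 0.5
    sigma_distort: 0.5
train:
  n_steps: 1000
  batch_size: 8
  lr: 0.001
  seed: 0
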