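# Demo run configuration: small synthetic cohort, scaled-down model.
# Any omitted key keeps the package default (full-scale tuned model,
# 0.5-40 Hz bandpass, 10 s windows at 50% overlap).
seed: 7
sim:
  fs: 180.0
  duration: 300.0
  n_patients: 8
  n_leads: 2
  class_probs: [0.4, 0.2, 0.2, 0.2]
  class_persistence: 0.95
model:
  n_gnn_layers: 1
  n_transformer_layers: 1
  d_model: 32
  heads: 4
  d_gnn: 16
  head_hidden: 32
  learning_rate: 0.001
training:
  max_epochs: 10
  test_frac: 0.25
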