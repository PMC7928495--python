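# Synthetic study system for `nichescreen simulate`.
# Three of twelve smooth layers drive a logistic suitability surface;
# presences are sampled proportionally to it.
grid_shape: [60, 60]
n_layers: 12
smoothness: 2.0          # Gaussian kernel sigma, in cells
cross_correlation: 0.25  # AR(1) neighbour correlation; omit for independent layers
true_variables: [env01, env05, env09]
true_coefficients:
  linear:
    env01: 3.0
    env05: -3.0
    env09: 3.0
n_presences: 150
seed: 1
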