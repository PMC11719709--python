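scenario: tree
seed: 1
scenario_args:
  cells_per_timepoint: 300
params:
  epsilon: 0.05
  lambda1: 1.0
  lambda2: 50.0
  growth_iters: 20
  emd_max_points: 150
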