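# Default synthetic scenario: superfamily-scale dataset shape.
# 200 tips, crown depth ~1.84 tree units (1 unit = 10^8 years), root at
# 9 autosome pairs with a simple XY system, rates per tree unit.
outdir: scarab_like_run
seed: 42
sim:
  n_tips: 200
  birth: 1.0
  death: 0.0
  tree_depth: 1.84
  root_k: 9
  root_system: simple
  k_min: 1
  k_max: 30
  scs_mode: true
  multi_record_fraction: 0.175
  n_trees: 3
  jitter_sd: 0.1
  params:
    fission: 0.3
    fusion: 0.7
    sa_fusion: 0.6
    reversion: 0.2
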