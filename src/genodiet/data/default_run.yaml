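# Default trial-scale pipeline configuration.
# 275 genotyped subjects; screening + pre-baseline dropout leaves ~145
# randomized. All omitted keys fall back to the package defaults.
simulation:
  n_screened: 275
alpha: 0.05
seed: 1
out_dir: genodiet_run
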