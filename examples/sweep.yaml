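# Attraction-range sweep for the single-chain equilibrium shape.
mode: equilibrium_shape
n_chains: 1
N: 500
M: 10
Cr: 5
shell_D1: 10.61
F_cond: 1.0
F_loop: 1.0
n_replicates: 2
production_time: 600.0
sample_every: 20.0
sweep:
  Delta: [0.5, 2.0, 3.0]
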