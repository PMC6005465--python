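# Two miniature chromosomes at the reference condensin parameters.
# Keys matching simulation-parameter names set the physics; the rest set
# the protocol.
mode: segregation
n_chains: 2
N: 500
M: 10
Cr: 5
shell_D1: 10.61          # 22.85 * (N/5000)^(1/3): reference per-chain density
F_cond: 1.0
Delta: 1.0
F_loop: 1.0
n_replicates: 3
production_time: 1000.0
sample_every: 20.0
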