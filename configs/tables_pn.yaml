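# 2/1 partially nested moderated-mediation study; grid is (n2_t, n1_t),
# control arm size n_c = n2_t * n1_t.
study: partially_nested
estimators: [fs, croon]
grid: [[30, 20], [40, 20], [50, 10], [50, 20], [50, 30], [80, 20], [80, 30], [100, 10], [100, 50]]
replications: 500
master_seed: 20260102
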