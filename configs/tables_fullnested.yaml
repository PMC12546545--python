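# Fully nested Monte Carlo study: three latent-interaction designs over the
# n2 x n1 grid, SAM-FS and SAM-Croon.
study: fully_nested
designs: [within, cross, between]
estimators: [fs, croon]
grid: [[30, 50], [60, 50], [90, 50], [30, 20], [60, 20], [90, 20]]
replications: 500
master_seed: 20260101
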