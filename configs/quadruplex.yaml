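# 90-mixture Latin-hypercube quadruplex: 21-level snap over each dye's
# linear range, 3 replicates, bootstrap-validated PLS1 (per dye) and PLS2
# (all four dyes at once). The full protocol below (1000/10000 bootstrap
# iterations) takes a while; scale n_boot_* down for a quick look.
recipe: quadruplex
seed: 1
m: 90
n_levels: 21
replicates: 3
additive_noise_sd: 0.01
multiplicative_noise_sd: 0.02
drift_amplitude: 0.05
n_boot_pls1: 1000
n_boot_pls2: 10000
a_max: 10
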