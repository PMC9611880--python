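# Dilution-series recipe: 7 levels (0.03 -> 0.002 mM) x 3 technical
# replicates per dye, SNV + PLS1 with 7-fold double cross-validation,
# pseudo-univariate LOD from the pooled held-out predictions.
recipe: simplex
seed: 1
additive_noise_sd: 0.01
multiplicative_noise_sd: 0.02
drift_amplitude: 0.05
replicates: 3
a_max: 10
lod_multiplier: 3.3
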