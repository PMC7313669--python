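model: trait_optimum
N: 450
n_loci: 100
start_freq: 0.05
s: null
effect_size: 0.04
optimum: null
optimum_distance: 1.1
fitness_sd: 0.3
min_fit: 0.5
max_fit: 4.5
heritability: 0.5
generations: 140
record_interval: 10
n_replicates: 500
root_seed: 1
n_haplotypes: 189
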