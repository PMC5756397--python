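# Strong-LD scenario: 20-SNP haplotype blocks with high template fidelity,
# exercising the sliding-window pruner. More individuals per population give
# stable r^2 estimates.
populations: [pop1, pop2, pop3, pop4]
f_per_population: [0.05, 0.10, 0.15, 0.20]
n_loci: 5000
n_individuals_per_pop: [20, 20, 20, 20]
discovery_panel:
  - [pop1, 4]
  - [pop2, 4]
ascertainment_maf_min: 0.05
pool_coverage_mean: 20.0
ancestral_freq_dist: {kind: beta, a: 0.5, b: 1.5}
population_tree: null
ld_block_size: 20
ld_decay: 0.95
missing_rate: 0.0
seed: 1
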