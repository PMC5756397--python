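# Null scenario: the "panel" is every individual of every population and no
# MAF cutoff is applied, so the array keeps every segregating locus and no
# ascertainment bias is introduced.
populations: [pop1, pop2, pop3, pop4, pop5, pop6, pop7, pop8]
f_per_population: [0.02, 0.05, 0.08, 0.12, 0.16, 0.20, 0.25, 0.30]
n_loci: 20000
n_individuals_per_pop: [10, 10, 10, 10, 10, 10, 10, 10]
discovery_panel:
  - [pop1, 10]
  - [pop2, 10]
  - [pop3, 10]
  - [pop4, 10]
  - [pop5, 10]
  - [pop6, 10]
  - [pop7, 10]
  - [pop8, 10]
ascertainment_maf_min: 0.0
pool_coverage_mean: 20.0
ancestral_freq_dist: {kind: beta, a: 0.5, b: 1.5}
population_tree: null
ld_block_size: 1
ld_decay: 0.0
missing_rate: 0.0
seed: 1
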