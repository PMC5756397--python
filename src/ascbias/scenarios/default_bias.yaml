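# Default ascertainment-bias scenario: eight drifted populations, an array
# designed from a two-population discovery panel (4 + 4 diploids) with a 5%
# panel-MAF cutoff, pooled resequencing at 20X. pop1/pop2 are wild-like
# high-diversity populations (smallest drift), pop3/pop4 are the panel lines.
populations: [pop1, pop2, pop3, pop4, pop5, pop6, pop7, pop8]
f_per_population: [0.02, 0.05, 0.08, 0.12, 0.16, 0.20, 0.25, 0.30]
n_loci: 50000
n_individuals_per_pop: [10, 10, 10, 10, 10, 10, 10, 10]
discovery_panel:
  - [pop3, 4]
  - [pop4, 4]
ascertainment_maf_min: 0.05
pool_coverage_mean: 20.0
ancestral_freq_dist: {kind: beta, a: 0.5, b: 1.5}
population_tree: null
ld_block_size: 1
ld_decay: 0.0
missing_rate: 0.005
seed: 1
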