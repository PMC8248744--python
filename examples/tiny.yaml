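chromosome_lengths: [500000, 300000, 200000]
snp_density: 0.002
n_pairs: 3
n_females: 120
pool_size: 120
n_generations: 10
burn_in_generations: 2
causal_loci:
  - [chr1, 250000, 0.5, 0.1]
cnv_locus: [chr2, 100801, 114000, 3]
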