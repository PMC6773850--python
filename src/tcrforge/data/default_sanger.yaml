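# Default Sanger-library emulation: three donors pooled into 442 dominant +
# 442 weak distinct clonotypes (884 total).  Usage weights skew the genes
# reported enriched per arm; residue-level effects are planted at documented
# candidate positions with moderate odds ratios.
n_donors: 3
n_clonotypes_per_phenotype: 442
chain_split: 0.5
cdr3_length_range: [8, 13]
seed: 1
v_usage_weights:
  dominant:
    TRAV38-2: 2.5
    TRBV7-8: 2.5
    TRBV5-1: 2.0
  weak:
    TRAV13-2: 2.5
    TRBV9: 2.0
    TRBV7-9: 2.0
    TRBV2: 2.0
planted_effects:
  - {chain: alpha, imgt_position: 96, amino_acid: L, odds_ratio: 4.0, baseline_freq: 0.25}
  - {chain: beta, imgt_position: 9, amino_acid: R, odds_ratio: 3.0, baseline_freq: 0.25}
  - {chain: beta, imgt_position: 10, amino_acid: Y, odds_ratio: 3.0, baseline_freq: 0.25}
background_variation:
  - {chain: alpha, imgt_position: 19, amino_acid: V, odds_ratio: 1.0, baseline_freq: 0.3}
  - {chain: beta, imgt_position: 43, amino_acid: Q, odds_ratio: 1.0, baseline_freq: 0.3}
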