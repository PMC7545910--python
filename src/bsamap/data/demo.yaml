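# Demo run: one 40-Mb chromosome, recessive locus at 20 Mb, the emulated
# study design (185 F2 plants, 21+21 bulks, mean depth 30).
seed: 1
genome:
  chr3: 40000000
simulate:
  causal_chrom: chr3
  causal_pos: 20000000
  cross_type: F2
  n_plants: 185
  bulk_size: 21
  snp_spacing: 50000
  cm_per_mb: 3.0
  mean_depth: 30
  error_rate: 0.001
filter:
  min_depth: 7
  min_index: 0.3
  depth_rule: both
  index_rule: either
scan:
  window: 1000000
  step: 10000
  ci_level: 99
  n_replicates: 10000
finemap:
  n_markers: 8
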