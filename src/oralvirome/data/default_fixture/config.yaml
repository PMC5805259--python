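bacterial_only_reads_per_sample: 15
n_samples: 12
n_taxa: 48
noise:
  coverage_alpha: 18.0
  coverage_beta: 2.0
  fail_rate: 0.02
  identity_mean: 95.0
  identity_sd: 4.0
  log10_evalue_max: -4.0
  log10_evalue_min: -30.0
  off_target_rate: 0.05
  read_length: 250
p_bacterial_homology:
  bacteriophage: 0.5
  eukaryotic_virus: 0.02
  prophage: 0.95
prophage_read_share: 0.92
reads_per_sample: 40
seed: 0
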