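pipeline:
  adapter_seq: AGATCGGAAGAGC
  ecori_site: GAATTC
  junction_cluster_tol: 5
  min_identity: 0.95
  min_junction_support: 10
  min_mate_len: 16
  min_overlap: 31
  min_split_segment: 16
  orf_min_codons: 100
  recovery_mode: centered
  recovery_window: 10000
  seed_k: 15
  trim_min_q: 15
  trim_mode: both_ends
  trim_window: 4
simulation:
  adapter_seq: AGATCGGAAGAGC
  at_window_length: 2000
  background_depth: 2.0
  base_quality: 35
  copy_number_bounds:
  - 10.0
  - 500.0
  ecori_pos: 1000
  host_at_fraction: 0.71
  host_background_at: 0.62
  host_chrom_length: 200000
  host_fragment_bounds:
  - 735
  - 1058
  insert_mean: 350.0
  insert_sd: 35.0
  intergenic_span:
  - 2640
  - 100
  microhomology_max: 3
  minicircle_total_bounds:
  - 1241
  - 1572
  n_at_windows_per_chrom: 6
  n_host_chrom: 5
  origin_motif: TAATATTAC
  per_base_error: 0.002
  read_length: 76
  seed: 1
  template_depth: 30.0
  virus_at: 0.59
  virus_length: 2845
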