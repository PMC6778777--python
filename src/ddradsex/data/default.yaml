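# Bundled default study design: 8 females + 8 males, 200 autosomal loci and
# 5 W-limited loci under female heterogamety, mean 15 reads per locus copy.
genome:
  n_autosomal_loci: 200
  n_w_specific_loci: 5
  n_z_or_x_loci: 0
  system: ZW
  locus_length_window: [450, 550]
  gc_content: 0.5
  snp_rate: 0.002
sim:
  read_length: 150
  barcode_length: 5
  mean_depth_per_locus: 15.0
  phred_quality: 37
demux:
  max_barcode_mismatch: 1
  window_fraction: 0.15
  min_window_mean_phred: 20.0
assembly:
  min_stack_depth: 3
  max_locus_mismatch: 4
  secondary_mismatch: 10
  catalog_mismatch: 0
scan:
  min_presence_frac: 1.0
  ratio_window: [0.3, 0.7]
  subset_sizes: [1, 2, 4, 8]
  replicates: 20
n_females: 8
n_males: 8
error_rate: 0.001
seed: 42
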