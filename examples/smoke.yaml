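# Small end-to-end demonstration cohort (runs in seconds).
seed: 7
outdir: smoke_out
spike_contig: lambda
coverage_regression: 10
coverage_swan: 10
coverage_dmr: 2
regression_covariates: [sex, race, bmi]
regression_alpha: 0.05
swan:
  window_width: 10
  step: 1
  q_alpha: 0.05
  min_per_window: 4
smooth:
  min_loci: 15
  min_width: 1000
  cluster_maxgap: 100000000
tstat:
  cutoff: 4.6
  dmr_maxgap: 300
  old_threshold_age: 50
  inclusive: true
simulation:
  n_subjects: 30
  n_cpgs: 600
  n_chroms: 2
  chrom_length: 400000
  island_count: 10
  island_width: 800
  n_genes: 16
  gene_length: 8000
  coverage_mean: 20
  logit_noise_sd: 0.3
  planted_linear: [[5, 0.25], [6, 0.25], [7, 0.25]]
  planted_wave: [[30, 50, 5, 15]]
  planted_dmr: [[100, 109, 25.0, 50.0]]
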