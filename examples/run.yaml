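# Full-pipeline configuration for `connrep run-all --config examples/run.yaml --out outdir`.
# Omit `input_dir` to simulate the cohort below; set it to a directory of
# <subject>_<scan>.txt files to analyze existing scans instead.
cohort:
  n_subjects: 12
  n_scans_per_subject: 4
  n_nodes: 15
  n_timepoints: 1200
  tr_seconds: 0.72
  var_order: 3
  population_coupling_density: 0.2
  subject_sd: 0.10
  scan_jitter_sd: 0.025
  innovation_sd: 1.0
  hrf_enabled: false
  rng_seed: 42
deconvolve: false        # enable together with hrf_enabled above
check_stationarity: true
methods: [pearson, partial, gc, te]
var_order: auto          # median-Schwarz selection, or a fixed integer
max_var_order: 6
te_max_lag: 5
n_inter_repeats: null    # default: one balanced inter quadruple per subject
seed: 42
correction: null         # null | bh | bonferroni
sqrt_matrix_nd: false
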