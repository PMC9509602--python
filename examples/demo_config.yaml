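# Fully synthetic demo study: 12 subjects x 2 sides, 40 species, planted
# stone-side effects (one species up 6-fold, one down 5-fold).
# Run with:  urotag run --config examples/demo_config.yaml --out demo_results/
seed: 7
simulate:
  n_phyla: 4
  n_genera: 12
  n_species: 40
  n_subjects: 12
  sigma_lognormal: 1.5
  subject_sd: 0.5
  sample_sd: 0.5
  effects:
    s01: 6.0
    s02: 0.2
  n_reads_per_sample: 8000
  error_rate: 0.001
  n_rate: 0.0005
  length_mean: 50000
params:
  n_trees: 100
  cv_n_trees: 30
  n_perm: 199
  top_n: 20
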