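seed: 11
out_dir: example_run
simulate:
  n_genes: 300
  n_cells: 800
  n_clusters: 4
  n_regulons: 2
  targets_per_regulon: 15
  library_log_mean: 6.2
  expanded_fraction: 0.3
  singleton_clusters: [3]
qc:
  min_features_per_cell: 50
  max_features_per_cell: 290
cluster:
  n_hvg: 200
  n_pcs: 20
  snn_k: 20
gem:
  branching: [2, 2, 2]
  n_iter: 100
  burn_in: 60
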