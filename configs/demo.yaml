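# Demo screen: 3 ORF libraries x 3 gates, 500 reads per pool, default
# nanopore-like error model. Run with:
#   sortscreen run-all --config configs/demo.yaml --out results/demo
seed: 11
out_dir: results/demo
simulate:
  orf_libraries: [ELP2, ELP4, BLA]
  n_cells: 30000
  reads_per_pool: 500
demux:
  max_dist: 4
  window: 150
  min_len: 2000
call:
  min_identity: 0.8
  min_coverage: 0.8
quantify:
  top: 5
  min_full_reads: 100
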