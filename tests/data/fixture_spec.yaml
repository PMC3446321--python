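# Provenance of the committed synthetic fixtures (all text, regenerable).
# toy_matrix.tsv / toy_lists.gmt / toy_gold.txt:
#   mexplorer.synthdata.gen_benchmark(GeneratorSpec(
#       n_genes=60, n_tfs=8, n_planted=2,
#       class_sizes={A: 8, B: 6}, sparsity=0.15, odds=5.0, seed=7))
# viability_small.tsv:
#   mexplorer.synthdata.gen_viability(
#       n_tested=3, n_wildtype=1, n_controls=1,
#       days=[0.3, 2.0, 7.0, 14.0], replicates=3, batches=2,
#       planted={strain01: {7.0: 4.0}}, seed=11)
benchmark:
  n_genes: 60
  n_tfs: 8
  n_planted: 2
  class_sizes: {A: 8, B: 6}
  sparsity: 0.15
  odds: 5.0
  seed: 7
viability:
  n_tested: 3
  n_wildtype: 1
  n_controls: 1
  days: [0.3, 2.0, 7.0, 14.0]
  replicates: 3
  batches: 2
  planted: {strain01: {7.0: 4.0}}
  seed: 11
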