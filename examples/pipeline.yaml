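# Demo configuration for `polkinetics all --config examples/pipeline.yaml --out run/`
seed: 7

simulate:
  n_genes: 40
  noise: poisson
  tt_depth: 10.0
  mnet_depth: 20.0
  nexus_depth: 150.0

analysis:
  # shallow synthetic signals: the antisense-ratio estimator uses every
  # transcribed position instead of the >= 100x-covered subset
  antisense_min_coverage: 0.0
  kmeans_boot: 50
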