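# Smoke-test configuration: standard analysis thresholds, scaled-down sizes.
stages: [simulate, design, enrich, annotate, motif, ase]
seed: 0
sim:
  iterations: 100
  n_transcripts: 60
  n_individuals: 10
  n_samples: 4
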