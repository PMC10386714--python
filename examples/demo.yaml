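# Demo pipeline configuration: a small knockout experiment end to end.
outdir: trfscope_demo
seed: 7
reference:
  n_species: 4
  n_m7g_targets: 2
  length: 76
fragments:
  depth_per_sample: 20000
cohorts:
  n_genes: 100
  planted:
    - gene: G0000
      effect_sd: 2.0
polysome:
  n_transcripts: 20
  shifted: [T0001, T0002]
diff:
  lfc_min: 2.0
  p_max: 0.05
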