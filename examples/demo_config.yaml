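# Demo pipeline configuration: a 1/8-scale synthetic alpha lobe.
# Run with:  alphalobe analyze --config examples/demo_config.yaml
outdir: scratch/demo-report
seed: 1
generator:
  n_kc_per_subtype:
    KC-ab-s: 60
    KC-ab-c-o: 17
    KC-ab-c-i: 33
    KC-ab-p: 10
  convergence_rate: 0.6
  rosette_rate: 0.7
radius: 300.0
coverage_radii: [0.0, 5000.0, 100.0]
min_expected: 0.5
df_adjust: 0
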