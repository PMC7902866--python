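# Demo configuration: small synthetic cohort, full pipeline.
# Run:  mcpain run --config examples/demo.yaml
#       mcpain sweep --config examples/demo.yaml
simulation:
  n_participants: 24
  n_rois: 10
  n_voxels: 400
  n_planted_edges: 5
  target_r2: 0.85
feature_set: mc
threshold: laser
mode: nested
seed: 7
out_dir: mcpain_out
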