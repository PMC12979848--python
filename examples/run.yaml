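# Demo pipeline configuration: synthetic modular network end to end.
# Run:  qgdm run --config examples/run.yaml --seed 0
synthetic:
  n_vertices: 24
  n_modules: 3
  p_intra: 0.6
  p_inter: 0.05
  feature_dim: 8
  feature_noise: 0.2

physics:
  coupling: 1.0          # gamma multiplying the extended graph Laplacian
  omega_default: 0.5     # on-site conformational splitting (energy / hbar)
  rate_dephasing: 0.1    # channel rates in units of the coupling
  rate_binding: 0.05
  rate_thermal: 0.01

measurement:
  lambda_decay: 1.0      # binding memory decay rate (1/time)
  horizon: 2.0           # scoring time t
  grid_step: 0.05
  threshold: 0.15

outputs:
  predictions_path: predictions.tsv
  report_path: report.json
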