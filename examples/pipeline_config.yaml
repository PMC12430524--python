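# Small end-to-end pipeline configuration (runs in under a minute).
# Drop the `study` overrides to run at the full study design
# (276 residues, 3 x 10,000 frames per variant, last 1000 retained).
drug: dabrafenib
seed: 7
study:
  n_residues: 60
  residue_offset: 448
  frames_per_trajectory: 300
  retain_last: 100
  planted: [phi455, psi460]
selection:
  n_rounds: 2
forest:
  n_trees: 25
  max_depth: 6
shap:
  background_size: 50
  max_rows: 100
convergence:
  window_size: 50
  n_windows: 2
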