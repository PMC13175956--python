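# Pipeline configuration for a desk-scale synthetic patient.
# Run:  gkplan run --config examples/config/micro.yaml --out runs/demo --seed 1
phantom:
  targets:
    - volume_cc: 0.3
      prescription_dose: 18.0
  grid_shape: [32, 32, 32]
  spacing_mm: [1.5, 1.5, 1.5]
  skull_semi_axes_mm: [18.0, 18.0, 18.0]
  shell_s_margin_mm: 2.0
  shell_g_margin_mm: 6.0
  calibration_dose: 18.0
seed: 1
candidate_method: hcp          # or grassfire
reference_count: 3             # isocenter count of the emulated historical plan
limit_mode: percent            # explicit | percent | ipred
limit_fraction: 1.0            # 0.6 = I0, 1.0 = I1, 1.4 = I2
weight_mode: approximate       # approximate | cutting_plane | cutting_plane_regularized | manual
prediction_noise_sd: 0.0       # Gy; >0 corrupts the synthetic prediction
dose_rate_scale: 2.5           # Gy/min delivered at the focus with all sectors open
cutting_plane_budget_s: 3600.0
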