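# Prostate-like full-arc planning example.
# Scenario geometry defaults come from the packaged scenario; objectives
# here mirror the packaged defaults (uniform target dose, OAR dose caps,
# target LET_d maximization via an intentionally high min-LET goal).
scenario:
  id: prostate-like

machine:
  min_mu: 0.02
  rotation_rpm: 1.0
  spot_switch_s: 0.002
  layer_switch_s: 0.6

objectives:
  - {roi: ctv, quantity: dose, sense: uniform, goal: 78.0, penalty: 100.0}
  - {roi: oar_left, quantity: dose, sense: max, goal: 60.0, penalty: 20.0}
  - {roi: oar_right, quantity: dose, sense: max, goal: 60.0, penalty: 20.0}
  - {roi: ctv, quantity: letd, sense: min, goal: 8.0, penalty: 60.0}

sequencing:
  coarse_spacing_deg: 20.0
  final_spacing_deg: 2.5
  final_layers_per_cp: 1
  lateral_spacing_mm: 5.0
  layer_spacing_cm: 0.5
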