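# Published constants: knee geometry, tissue properties and model settings
# taken from the literature the simulators implement.  Units: mm, MPa,
# degrees.  Values with no literature source live in
# calibrated_defaults.yaml instead - the two provenances are never mixed.
geometry:
  condyle_radius: 4.0          # mm
  tendon_thickness: 1.75       # mm
materials:
  cartilage: {young_modulus: 6.1, poisson_ratio: 0.497}
  tendon_matrix: {young_modulus: 6.1, poisson_ratio: 0.4}
  tendon_fiber: {young_modulus: 800.0, poisson_ratio: 0.4}
load:
  quadriceps_pull_mm: 1.0      # prescribed contraction displacement
sweep_angles_deg: [30, 45, 60, 90, 110]
scenarios:                     # share of time at each sweep angle
  weighting_high_flexion: [0.05, 0.10, 0.15, 0.25, 0.45]
  weighting_low_flexion: [0.60, 0.25, 0.09, 0.05, 0.01]
  heavily_weighting_high_flexion: [0.01, 0.05, 0.09, 0.25, 0.60]
simp:
  penalization: 3.0
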