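# Calibrated stand-in parameters: quantities with no published value,
# chosen by trial and error so that the default runs reproduce the
# qualitative patella-onset behaviour (see docs/methods.md for the
# calibration rationale).  Units: mm, dimensionless simulation time tau,
# ng/ml for concentrations, cells per reference volume for b.
geometry:
  quadriceps_segment_length: 6.0   # mm, free parameter (never stated)
  patellar_segment_length: 6.0     # mm
  femur_depth: 2.0                 # mm, radial depth of the femoral cartilage
  n_through_thickness: 8
  n_along_length: 120
  n_femur_radial: 4
  scx_start_frac: 0.0              # initial Scx domain: proximal tendon
  scx_end_frac: 0.28               #   (quadriceps side, next to the muscle)
biochem:
  diffusion:        # mm^2 / tau
    TGFB: 0.5
    BMP: 2.0e-3
    FGF: 0.25
    GDF5: 6.0e-4
  sources:          # ng/ml held at the source node sets
    TGFB: 10.0
    BMP: 10.0
    FGF: 10.0
    GDF5: 10.0
  low_diffusion_factor:            # diffusivity multiplier inside cartilage
    TGFB: 0.1
    BMP: 0.1
    FGF: 0.1
    GDF5: 1.0      # the interzone marker is not slowed by cartilage
  mu: 0.06          # Scx-cell diffusion, mm^2 / tau
  chi: 0.02         # chemotactic coefficient, mm^2 / (tau ng/ml)
  b0: 1.0           # initial Scx density in the Scx domain
  growth_rate: 0.05 # logistic proliferation r, 1/tau (Fisher-type front)
  b_max: 1.0        # carrying capacity of the Scx population
  thresholds:
    b_c_th: 0.25
    s_bmp_th: 5.0
    s_fgf_th: 2.0
    s_gdf5_th: 6.5
  b_sense: 0.125    # muscle sensing threshold (b_c_th / 2)
  sense_layers: 2
  dt: 0.05          # tau
  n_steps: 9400
  snapshot_every: 200
carter:
  threshold_fraction: 0.3   # sigma_hyd_cart = -0.3 * |peak compressive|
  epsilon_tensile_max: 0.08 # "low tensile strain" cap (no printed value)
  stress_phase: matrix      # pressure felt by cells between the fibers
simp:
  volume_fraction: 0.4
  rho_min: 0.001
  move_limit: 0.2
  damping: 0.5
  max_iterations: 200
  change_tolerance: 0.01
  filter_radius: 1.5        # mean element lengths; 0 disables
  scale_fibers: true
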