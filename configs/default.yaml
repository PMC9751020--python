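# Default run configuration (all values shown are also the built-in
# defaults; an empty file behaves identically).  Units are encoded in
# the key names.
seed: 0

geometry:
  grid_nx: 561                 # pixels along the beam (x)
  grid_ny: 561                 # pixels lateral (y); head centred on the axis
  dx_mm: 0.5                   # pixel size; must resolve points_per_wavelength
  brain_outer_radius_mm: 85.0  # outer skull radius of the simplified head
  skull_mm: [5.4, 7.6, 10.5]   # skull annulus thicknesses swept by the pipeline
  standoff_mm: 40.0            # arc apex -> outer skull boundary, on axis
  aperture_mm: 64.0            # curved transducer aperture (device datasheet)
  roc_mm: 63.2                 # radius of curvature = focal distance
  apex_margin_mm: 15.0         # water gap left of the arc apex
  frequency_khz: 250.0         # carrier frequency
  amplitude_kpa: 100.0         # surface pressure amplitude of the source
  points_per_wavelength: 4.0   # discretisation bound used for validation

media:                         # sound speed (m/s), density (kg/m^3),
  water: {sound_speed: 1481.0, density: 998.0,  alpha0: 0.002}  # alpha0 in
  skull: {sound_speed: 2820.0, density: 1732.0, alpha0: 7.75}   # dB/(MHz cm)
  brain: {sound_speed: 1500.0, density: 1000.0, alpha0: 0.8}

solver:
  cfl: 0.5                     # dt = cfl * dx / c_max
  pml_px: 20                   # absorbing boundary thickness, pixels
  absorption_exponent: 1.0     # gamma in alpha0 * f_MHz^gamma
  window_us: 500.0             # macroscale pulsing window
  duty_cycles: [0.4, 0.5, 0.6, 0.7, 0.8, 0.9]

neuron:
  bls: {}                      # SI-unit overrides of the sonophore constants
  rs: {}                       # SI-unit overrides of the RS membrane

roi:
  y_rows_mm: [-10.19, -5.56, -0.92]  # lateral sampling rows
  n_columns: 5                 # axial columns (total 15 positions)
  column_spacing_mm: 5.0
  mirror: false                # sample the +y side instead

protocol:
  prf_hz: 500.0                # microscale pulse repetition frequency
  duration_ms: 100.0           # sonication duration per neuron run
  table_pa_step_kpa: 10.0      # lookup-table pressure resolution
  sonic_dt_us: 1.0             # effective-variable integrator step
  spike_threshold_mv: 0.0
  spike_refractory_ms: 1.0

output:
  out_dir: results
  safety_threshold_w_cm2: 3.0  # physiotherapy-standard intensity bound
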