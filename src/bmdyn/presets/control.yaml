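# Control (untreated) developing hair follicle.
# Turnover rates are first-order per-minute constants back-computed from the
# measured recovery endpoints (tip half-life 205 min); strain rates from the
# endpoint length changes as ln(1 + delta) / T.
name: control
geometry:
  stalk_length: 40.0
  bulb_radius: 15.0
  spacing: 0.5
  junction_band: 5.0
turnover:        # per minute
  tip: 3.3812e-3          # ln 2 / 205 min
  lower_stalk: 1.2446e-3
  upper_stalk: 8.0e-4     # not printed; interpolated between lower stalk and junction
  junction: 3.4558e-4
strain:          # per minute
  tip: 6.2470e-4          # ln(1.30) / 420 min  -> +30% over 7 h
  lower_stalk: 3.4875e-4  # ln(1.22) / 570 min  -> +22% over 9.5 h
  upper_stalk: 0.0        # endpoint ~ -3% is within noise; default 0
  junction: 0.0
thickness:       # Gaussian cross-section sigma, um
  tip: 1.0
  lower_stalk: 1.013      # junction/upper measured 55% and 53% thicker than tip/lower
  upper_stalk: 1.55
  junction: 1.55
division:
  rates:         # events / cell / hour
    tip: 0.08
    lower_stalk: 0.05
    upper_stalk: 0.02
    junction: 0.01
  angle_mixture: # daughter-allocation angle classes
    horizontal: 0.500
    oblique: 0.104
    perpendicular: 0.396
  s_phase_rates: # per hour, drives EdU-style labeling
    tip: 0.25
    lower_stalk: 0.15
    upper_stalk: 0.06
    junction: 0.03
  s_phase_duration: 60.0
imaging:
  pixel_size: 0.5
  frame_interval: 10.0
  image_shape: [192, 192]
  photon_scale: 100.0
  read_sigma: 0.01
  background: 0.1
  z_planes: 1
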