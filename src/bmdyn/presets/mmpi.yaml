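# Broad-spectrum MMP inhibition (batimastat-type): turnover and expansion
# suppressed, divisions shifted perpendicular, slow bulb widening.
# Non-tip turnover rates scale by the same factor as the tip (0.0722);
# the radial (bulb-widening) rate is a geometric proxy for perpendicular-
# division cell influx, not a mechanical model.
name: mmpi
geometry:
  stalk_length: 40.0
  bulb_radius: 15.0
  spacing: 0.5
  junction_band: 5.0
turnover:        # per minute
  tip: 2.4425e-4          # ~5% recovery at 210 min
  lower_stalk: 8.99e-5
  upper_stalk: 5.78e-5
  junction: 2.50e-5
strain:          # per minute
  tip: 1.3873e-4          # ln(1.06) / 420 min -> +6% over 7 h
  lower_stalk: 0.0
  upper_stalk: 0.0
  junction: 0.0
thickness:
  tip: 1.0
  lower_stalk: 1.013
  upper_stalk: 1.55
  junction: 1.55
division:
  rates:         # slightly reduced division frequency
    tip: 0.064
    lower_stalk: 0.04
    upper_stalk: 0.016
    junction: 0.008
  angle_mixture:
    horizontal: 0.139
    oblique: 0.111
    perpendicular: 0.750
  s_phase_rates: # reduced at tip/lower stalk; upper stalk unchanged
    tip: 0.15
    lower_stalk: 0.09
    upper_stalk: 0.06
    junction: 0.03
  s_phase_duration: 60.0
radial_rate: 1.8994e-4    # ln(1.2) / 960 min bulb-radius growth
imaging:
  pixel_size: 0.5
  frame_interval: 10.0
  image_shape: [192, 192]
  photon_scale: 100.0
  read_sigma: 0.01
  background: 0.1
  z_planes: 1
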