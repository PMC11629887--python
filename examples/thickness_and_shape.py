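"""BM thickness morphometry and the follicle shape factor.

Thickness uses the area-over-long-axis convention on a 7.5-um window
(supra-threshold cross-section area divided by window length).  The shape
factor S = follicle length / bulb width distinguishes cylindrical
elongation (S rising) from the widened shape under MMP inhibition.
"""

import bmdyn as bd

# --- thickness: junction/upper stalk vs tip ------------------------------
profile = bd.ThicknessProfile({"tip": 1.0, "lower_stalk": 1.0,
                               "upper_stalk": 1.55, "junction": 1.55})
state = bd.build_follicle(thickness=profile)
img = bd.render_frame(state, bd.ImagingConfig(photon_scale=0, read_sigma=0))
trace = bd.CenterlineTrace(xy=state.xy, arc=state.s)
apex = state.total_arclength / 2
t_tip = bd.measure_thickness(img, trace, (apex - 3.75, apex + 3.75))
t_jn = bd.measure_thickness(img, trace, (10.25, 17.75))
print(f"thickness tip            : {t_tip:.2f} um")
print(f"thickness junction/upper : {t_jn:.2f} um "
      f"(+{100 * (t_jn / t_tip - 1):.0f}% over the tip)")

# --- shape factor time course: control vs MMPi ---------------------------
for preset in ("control", "mmpi"):
    p = bd.load_preset_params(preset)
    st = bd.build_follicle(strain=bd.StrainProfile(p["strain"]),
                           radial_rate=p.get("radial_rate", 0.0))
    states, times = [st], [0.0]
    for h in range(16):
        st = bd.run_dynamics(st, 60.0)
        states.append(st)
        times.append(60.0 * (h + 1))
    df = bd.shape_timecourse(states, times)
    print(f"{preset:8s} S(0 h) = {df['S'].iloc[0]:.2f}  "
          f"S(16 h) = {df['S'].iloc[-1]:.2f}  (dS = {df['dS'].iloc[-1]:+.2f})")
print("\nControl follicles elongate (S rises); the MMP-inhibited preset "
      "stalls and widens\n(S flat or falling), reproducing the disrupted "
      "morphogenesis readout.")
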