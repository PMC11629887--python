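"""FRAP turnover quantification on a simulated tip-region basement membrane.

Bleaches a 15-um ROI on a BM with first-order collagen-IV turnover at the
tip rate (half-life 205 min), renders a noisy 10-min-interval time lapse,
and runs the full extraction: centerline trace -> normalized recovery ->
linear fit.
"""

import numpy as np

import bmdyn as bd

K_TIP = np.log(2) / 205.0  # per minute

scenario = bd.frap_scenario(k=K_TIP, region="tip", seed=0, duration=230.0)
curve, fit = bd.frap_pipeline(scenario)

print(f"turnover rate k        : {K_TIP:.6f} /min (half-life 205 min)")
print(f"recovery at 205 min    : {100 * curve.value_at(205.0):.1f} %  "
      "(expected ~50% -- half the bleached collagen replaced)")
print(f"linear-fit slope       : {fit.slope * 100:.3f} %/min")
print(f"fitted t50             : {fit.t50:.0f} min"
      + ("  (extrapolated)" if fit.t50_extrapolated else ""))
exp = bd.fit_recovery_exponential(curve)
print(f"exponential cross-check: k = {exp['k']:.6f} /min "
      "(should recover the simulated rate)")
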