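"""Bleached-edge fiducial tracking of basement-membrane expansion.

Bleaches four stripes that compartmentalize one flank of the follicle BM
(upper stalk / lower stalk / tip), re-bleaches every 150 min so the edges
stay sharp, and tracks each compartment's length for 7 h.  Control tip
strain is ln(1.3)/420 per minute (+30% over 7 h); the MMP-inhibition preset
uses ln(1.06)/420 (+6%).
"""

import bmdyn as bd

for preset, strain in [("control", {"tip": 0.0006247}),
                       ("mmpi", {"tip": 0.00013873})]:
    scenario = bd.expansion_scenario(strain=strain, preset=preset, seed=0)
    tracks = bd.expansion_pipeline(scenario)
    print(f"--- {preset} ---")
    for tr in tracks:
        pct = bd.percent_length_change(tr, 0.0, 420.0)
        print(f"  {tr.region:<12s} L0 = {tr.lengths[0]:6.2f} um   "
              f"change over 7 h = {pct:+6.2f} %")
print("\nThe tip compartment expands ~30% in control but only ~6% under "
      "MMP inhibition;\nstalk compartments (zero strain here) stay within "
      "the ~1% measurement floor.")
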