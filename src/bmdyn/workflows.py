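"""End-to-end workflow runners: simulate a scenario and quantify it.

Thin conveniences over the module-level operations, so examples, tests and
batch scripts run the full simulate -> trace -> measure chain in one call.
"""

from __future__ import annotations

import numpy as np

from .expansion import CompartmentTrack, track_compartments
from .frap import RecoveryCurve, RecoveryFit, fit_recovery, normalize_recovery, trace_centerline
from .imaging import simulate_experiment
from .scenario import Scenario


def frap_pipeline(scenario: Scenario, roi_id: str = "FRAP"
                  ) -> tuple[RecoveryCurve, RecoveryFit]:
    """Simulate a FRAP scenario and return its normalized curve and fit."""
    series, log, manifest = simulate_experiment(scenario)
    traces = [trace_centerline(None, None, manifest=manifest, frame_index=i)
              for i in range(len(series.timestamps))]
    curve = normalize_recovery(series, log, roi_id, traces, manifest=manifest)
    return curve, fit_recovery(curve)


def expansion_pipeline(scenario: Scenario) -> list[CompartmentTrack]:
    """Simulate a compartmentalized-bleach scenario and track compartments."""
    series, log, manifest = simulate_experiment(scenario)
    traces = [trace_centerline(None, None, manifest=manifest, frame_index=i)
              for i in range(len(series.timestamps))]
    return track_compartments(series, log, traces, manifest=manifest)


def mean_frap_readout(k: float, t_read: float, seeds,
                      duration: float = 230.0) -> float:
    """Seed-averaged normalized recovery (percent) at ``t_read`` minutes."""
    from .scenario import frap_scenario

    vals = [frap_pipeline(frap_scenario(k=k, seed=int(s), duration=duration)
                          )[0].value_at(t_read) for s in seeds]
    return float(100.0 * np.mean(vals))


def mean_tip_expansion(seeds, strain: dict[str, float] | None = None,
                       turnover: dict[str, float] | None = None,
                       preset: str = "control", duration: float = 420.0
                       ) -> float:
    """Seed-averaged percent tip-compartment length change at ``duration``."""
    from .expansion import percent_length_change
    from .scenario import expansion_scenario

    vals = []
    for s in seeds:
        tracks = expansion_pipeline(expansion_scenario(
            strain=strain, turnover=turnover, preset=preset, seed=int(s),
            duration=duration))
        tip = next(t for t in tracks if t.region == "tip")
        vals.append(percent_length_change(tip, 0.0, duration))
    return float(np.mean(vals))
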