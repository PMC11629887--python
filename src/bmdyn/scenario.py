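"""Scenario configuration: named presets and experiment builders.

A :class:`Scenario` bundles everything one simulated imaging session needs:
follicle geometry, turnover/strain/division parameters, optical events
(bleach / photoconversion, with optional scheduled re-bleach rounds) and the
imaging configuration.  Scenarios load from YAML; two named presets ship
with the package:

``control``
    Spatially graded dynamics of normal morphogenesis: fast tip turnover
    (half-life 205 min), slow junction turnover, ~30% tip elongation over
    7 h, mixed division angles (50% horizontal / 39.6% perpendicular).
``mmpi``
    Broad-spectrum MMP inhibition: turnover and expansion suppressed
    (~5% tip recovery at 3.5 h, ~6% tip elongation over 7 h), divisions
    shifted perpendicular (75%), and a slow bulb-widening proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .follicle import (
    DivisionModel,
    FollicleGeometry,
    FollicleState,
    StrainProfile,
    ThicknessProfile,
    TurnoverProfile,
    build_follicle,
    region_boundaries,
)
from .imaging import ImagingConfig


@dataclass
class Scenario:
    """A fully specified simulated imaging session."""

    name: str = "custom"
    geometry: FollicleGeometry = field(default_factory=FollicleGeometry)
    turnover: TurnoverProfile | None = None
    strain: StrainProfile | None = None
    division: DivisionModel | None = None
    thickness: ThicknessProfile | float = 1.0
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    duration: float = 240.0       # minutes after t = 0 (first event epoch)
    pre_time: float = 30.0        # minutes of pre-event imaging
    dt: float = 1.0               # integrator step, minutes
    events: list[dict] = field(default_factory=list)
    rebleach_period: float | None = None
    rebleach_efficiency: float = 1.0
    n_cells: int = 0
    cell_slip: float = 0.0
    mkikgr_mode: bool = False
    radial_rate: float = 0.0
    render_cells: bool = False
    seed: int = 0

    def build_state(self) -> FollicleState:
        state = build_follicle(
            geometry=self.geometry, turnover=self.turnover, strain=self.strain,
            division=self.division, seed=self.seed, thickness=self.thickness,
            n_cells=self.n_cells, mkikgr_mode=self.mkikgr_mode,
            radial_rate=self.radial_rate,
        )
        if self.cell_slip:
            for c in state.cells:
                c.slip = self.cell_slip
        return state

    def profile_summary(self) -> dict:
        out: dict = {"name": self.name, "seed": self.seed}
        if self.turnover is not None:
            out["turnover"] = dict(self.turnover.rates)
        if self.strain is not None:
            out["strain"] = dict(self.strain.rates)
        return out


# --------------------------------------------------------------------------
# YAML loading
# --------------------------------------------------------------------------

def load_scenario(source: str | Path | dict, **overrides) -> Scenario:
    """Load a scenario from a preset name, YAML path, or parsed dict."""
    if isinstance(source, dict):
        data = source
    else:
        p = Path(source)
        if p.suffix in {".yaml", ".yml"} and p.exists():
            data = yaml.safe_load(p.read_text())
        else:
            data = yaml.safe_load(
                resources.files("bmdyn.presets").joinpath(f"{source}.yaml")
                .read_text())
    return _scenario_from_dict(data, **overrides)


def _scenario_from_dict(data: dict, **overrides) -> Scenario:
    data = {**data, **overrides}
    kwargs: dict = {"name": data.get("name", "custom")}
    if "geometry" in data:
        kwargs["geometry"] = FollicleGeometry(**{
            k: tuple(v) if k == "origin" else v
            for k, v in data["geometry"].items()})
    if data.get("turnover"):
        kwargs["turnover"] = TurnoverProfile(data["turnover"])
    if data.get("strain"):
        kwargs["strain"] = StrainProfile(data["strain"])
    if data.get("thickness"):
        th = data["thickness"]
        kwargs["thickness"] = (ThicknessProfile(th) if isinstance(th, dict)
                               else float(th))
    if data.get("division"):
        dv = dict(data["division"])
        kwargs["division"] = DivisionModel(
            rates=dv.get("rates", {}),
            angle_mixture=dv.get("angle_mixture",
                                 {"horizontal": 0.5, "oblique": 0.1,
                                  "perpendicular": 0.4}),
            s_phase_rates=dv.get("s_phase_rates", {}),
            s_phase_duration=dv.get("s_phase_duration", 60.0),
        )
    if "imaging" in data:
        im = dict(data["imaging"])
        if "image_shape" in im:
            im["image_shape"] = tuple(im["image_shape"])
        kwargs["imaging"] = ImagingConfig(**im)
    for key in ("duration", "pre_time", "dt", "events", "rebleach_period",
                "rebleach_efficiency", "n_cells", "cell_slip", "mkikgr_mode",
                "radial_rate", "render_cells", "seed"):
        if key in data:
            kwargs[key] = data[key]
    return Scenario(**kwargs)


def load_preset_params(name: str) -> dict:
    """Raw parameter dict of a shipped preset (``control`` or ``mmpi``)."""
    text = resources.files("bmdyn.presets").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


# --------------------------------------------------------------------------
# experiment builders
# --------------------------------------------------------------------------

def frap_scenario(k: float | dict[str, float], *, region: str = "tip",
                  roi_length: float = 15.0, efficiency: float = 1.0,
                  duration: float = 230.0, frame_interval: float = 10.0,
                  seed: int = 0, noise: bool = True,
                  preset: str | None = None) -> Scenario:
    """Single-bleach FRAP protocol on one region's BM.

    ``k`` is a uniform first-order turnover rate (per minute) or a
    per-region rate dict.  One ROI of ``roi_length`` um (the imaging
    protocol uses 15 +- 2 um) is bleached at t = 0 at the center of
    ``region``; frames run from -30 min to ``duration`` at
    ``frame_interval`` (the FRAP videos were acquired roughly every
    10 min).
    """
    base = load_preset_params(preset) if preset else {}
    turnover = (TurnoverProfile.uniform(k) if np.isscalar(k)
                else TurnoverProfile(k))
    geometry = FollicleGeometry()
    probe = build_follicle(geometry=geometry)
    center = _region_center(probe, region)
    imaging = ImagingConfig(frame_interval=frame_interval,
                            photon_scale=100.0 if noise else 0.0,
                            read_sigma=0.01 if noise else 0.0)
    return Scenario(
        name=f"frap-{region}",
        geometry=geometry,
        turnover=turnover,
        strain=StrainProfile(base["strain"]) if base.get("strain") else None,
        imaging=imaging,
        duration=duration,
        pre_time=30.0,
        events=[{"time": 0.0, "kind": "bleach", "efficiency": efficiency,
                 "id": "FRAP", "roi": {"center": center, "length": roi_length}}],
        seed=seed,
    )


def expansion_scenario(strain: dict[str, float] | StrainProfile | None = None,
                       *, turnover: dict[str, float] | None = None,
                       duration: float = 420.0, frame_interval: float = 30.0,
                       rebleach_period: float | None = 150.0,
                       stripe_width: float = 3.0, seed: int = 0,
                       noise: bool = True, preset: str = "control",
                       strain_overrides: dict[str, float] | None = None
                       ) -> Scenario:
    """Compartmentalized-BM expansion protocol (bleached-edge fiducials).

    Four stripes are bleached at t = 0 at the region boundaries of one
    flank (junction|upper, upper|lower, lower|tip) plus the far tip bend
    point, delimiting upper-stalk, lower-stalk and tip compartments.
    Re-bleach rounds every ``rebleach_period`` minutes (the live protocol
    re-bleached every 2-3 h) re-draw the ROIs along the advected edges.
    """
    base = load_preset_params(preset)
    strain_d = dict(base.get("strain", {}))
    if isinstance(strain, StrainProfile):
        strain_prof = strain
    else:
        if strain is not None:
            strain_d = dict(strain)
        if strain_overrides:
            strain_d.update(strain_overrides)
        strain_prof = StrainProfile(strain_d) if strain_d else None
    turnover_d = turnover if turnover is not None else base.get("turnover", {})
    geometry = FollicleGeometry()
    probe = build_follicle(geometry=geometry)
    # stripe centers: junction|upper, upper|lower, lower|tip, tip|lower (far)
    regs = region_boundaries(probe)
    jb_up = regs[0][2]
    up_lo = regs[1][2]
    lo_tip = regs[2][2]
    tip_far = regs[3][2]
    stripes = [(c - stripe_width / 2, c + stripe_width / 2)
               for c in (jb_up, up_lo, lo_tip, tip_far)]
    # three z planes, averaged at measurement time (the live protocol reads
    # line intensities averaged over three z planes)
    imaging = ImagingConfig(frame_interval=frame_interval,
                            photon_scale=100.0 if noise else 0.0,
                            read_sigma=0.01 if noise else 0.0,
                            z_planes=3)
    return Scenario(
        name=f"expansion-{preset}",
        geometry=geometry,
        turnover=TurnoverProfile(turnover_d) if turnover_d else None,
        strain=strain_prof,
        imaging=imaging,
        duration=duration,
        pre_time=30.0,
        events=[{"time": 0.0, "kind": "bleach", "efficiency": 1.0,
                 "id": "COMPART", "roi": {"arc": [list(iv) for iv in stripes]},
                 "stripes": True}],
        rebleach_period=rebleach_period,
        seed=seed,
    )


def _region_center(state: FollicleState, region: str) -> float:
    for lab, lo, hi in region_boundaries(state):
        if lab == region:
            return (lo + hi) / 2.0
    raise ConfigError(f"unknown region {region!r}")
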