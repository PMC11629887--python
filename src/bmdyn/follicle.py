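"""Generative model of a growing, turning-over basement membrane.

The developing hair follicle is represented as a 1-D material curve (the
basement membrane, BM) laid out as a "U": two parallel stalk segments joined
by a semicircular bulb.  Material points carry an arc coordinate ``s`` (from
one epidermal junction, through the tip, to the opposite junction), a
labeled-protein fraction ``g`` (eGFP-collagen-IV proxy), a photoconverted
fraction ``r`` (mKikGR red pool), and a local cross-section width ``w``
(Gaussian sigma, micrometres).

Dynamics couple two first-order processes with spatial gradients:

* turnover -- labeled protein is replaced at a per-minute rate ``k(s)``:
  ``dg/dt = k (1 - g - r)``, ``dr/dt = -k r`` (incorporation balances
  removal, unit steady state);
* expansion -- each material segment elongates at a fractional strain rate
  ``eps(s)`` per minute, integrated exactly as ``exp(eps * dt)`` per step.

Epithelial basal cells are advected with the BM (arc-anchored, optional slip
velocity) and divide stochastically with a per-region rate and a
controllable daughter-allocation angle mixture.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, RangeError, StepSizeError

REGIONS = ("junction", "upper_stalk", "lower_stalk", "tip")

#: Daughter-allocation angle classes, degrees relative to the BM tangent.
ANGLE_CLASSES = {
    "horizontal": (0.0, 30.0),
    "oblique": (30.0, 60.0),
    "perpendicular": (60.0, 90.0),
}


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FollicleGeometry:
    """U-shape layout parameters (micrometres).

    ``stalk_length`` is the straight segment from the epidermal junction to
    the bend point; ``bulb_radius`` the semicircular tip radius;
    ``junction_band`` the terminal band at each open end assigned the
    ``junction`` region label.  ``origin`` places the bulb axis (x) and the
    junction line (y) in the physical frame, y increasing downward (the
    growth direction, matching image coordinates).
    """

    stalk_length: float = 40.0
    bulb_radius: float = 15.0
    spacing: float = 0.5
    junction_band: float = 5.0
    origin: tuple[float, float] = (48.0, 20.0)

    def __post_init__(self) -> None:
        if self.stalk_length <= 0 or self.bulb_radius <= 0:
            raise InvalidParameterError("stalk_length and bulb_radius must be > 0")
        if not (0 < self.spacing <= 0.5):
            raise InvalidParameterError("point spacing must be in (0, 0.5] um")
        if self.junction_band < 0 or self.junction_band >= self.stalk_length:
            raise InvalidParameterError("junction_band must be in [0, stalk_length)")


class RegionProfile:
    """Continuous per-region profile over arc length.

    A plateau value per region with linear transition ramps of half-width
    ``ramp_halfwidth`` at region boundaries.  Profiles are *material*
    fields: they are anchored to the region boundaries of the initial
    configuration and advect with the tissue, so bleached or tracked
    material keeps its local rates as the follicle grows (a material
    compartment under constant strain elongates exactly exponentially).
    """

    def __init__(self, rates: dict[str, float], ramp_halfwidth: float = 1.0):
        unknown = set(rates) - set(REGIONS)
        if unknown:
            raise InvalidParameterError(f"unknown region(s): {sorted(unknown)}")
        self.rates = {reg: float(rates.get(reg, 0.0)) for reg in REGIONS}
        self.ramp_halfwidth = float(ramp_halfwidth)

    @classmethod
    def uniform(cls, value: float) -> "RegionProfile":
        return cls({reg: value for reg in REGIONS})

    def __call__(self, state: "FollicleState", s: np.ndarray,
                 material: bool = True) -> np.ndarray:
        """Evaluate at coordinates ``s``.

        ``material=True`` (the default) interprets ``s`` as material
        (initial-configuration) arc coordinates and anchors the profile to
        the initial region boundaries; ``material=False`` anchors to the
        current geometric boundaries.
        """
        bounds = (state.material_boundaries if material
                  and state.material_boundaries is not None
                  else region_boundaries(state))
        hw = self.ramp_halfwidth
        xs: list[float] = []
        ys: list[float] = []
        total = bounds[-1][2]
        # nodes: domain start, then a pair of nodes straddling each boundary
        labels = [lab for lab, lo, hi in bounds]
        edges = [lo for lab, lo, hi in bounds][1:]  # interior boundaries
        xs.append(0.0)
        ys.append(self.rates[labels[0]])
        for b, left_lab, right_lab in zip(edges, labels[:-1], labels[1:]):
            xs.extend([b - hw, b + hw])
            ys.extend([self.rates[left_lab], self.rates[right_lab]])
        xs.append(total)
        ys.append(self.rates[labels[-1]])
        return np.interp(np.asarray(s, dtype=float), xs, ys)


class TurnoverProfile(RegionProfile):
    """First-order label replacement rate ``k(s)``, per minute (>= 0)."""

    def __init__(self, rates: dict[str, float], ramp_halfwidth: float = 1.0):
        super().__init__(rates, ramp_halfwidth)
        if any(v < 0 for v in self.rates.values()):
            raise InvalidParameterError("turnover rates must be >= 0")


class StrainProfile(RegionProfile):
    """Fractional elongation rate ``eps(s)`` per minute (may be negative)."""


class ThicknessProfile(RegionProfile):
    """Cross-section Gaussian sigma per region, micrometres (> 0)."""

    def __init__(self, sigmas: dict[str, float], ramp_halfwidth: float = 1.0):
        super().__init__(sigmas, ramp_halfwidth)
        if any(v <= 0 for v in self.rates.values()):
            raise InvalidParameterError("thickness sigmas must be > 0")


@dataclass(frozen=True)
class DivisionModel:
    """Stochastic division parameters.

    ``rates`` -- events per cell per hour, keyed by region.
    ``angle_mixture`` -- probabilities over the three allocation-angle
    classes (horizontal [0, 30), oblique [30, 60], perpendicular (60, 90]);
    must sum to 1.  ``s_phase_rates`` (per hour) drive EdU-style S-phase
    entry; ``s_phase_duration`` is how long a cell stays in S phase.
    """

    rates: dict[str, float] = field(default_factory=dict)
    angle_mixture: dict[str, float] = field(
        default_factory=lambda: {"horizontal": 0.5, "oblique": 0.1, "perpendicular": 0.4}
    )
    s_phase_rates: dict[str, float] = field(default_factory=dict)
    s_phase_duration: float = 60.0
    daughter_separation: float = 6.0

    def __post_init__(self) -> None:
        tot = sum(self.angle_mixture.get(c, 0.0) for c in ANGLE_CLASSES)
        if abs(tot - 1.0) > 1e-9:
            raise InvalidParameterError("angle mixture probabilities must sum to 1")


@dataclass
class Cell:
    """An epithelial basal cell anchored to the BM at arc coordinate s."""

    id: int
    anchor: float
    slip: float = 0.0  # um/min relative to the BM; 0 = fully coupled
    state: str = "interphase"
    parent: int | None = None
    edu: bool = False
    s_phase_until: float = -np.inf


@dataclass
class DivisionEvent:
    """A completed division: time, mother, daughter centroids, BM anchor."""

    time: float
    mother_id: int
    daughter_a: tuple[float, float]
    daughter_b: tuple[float, float]
    s: float


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------

@dataclass
class FollicleState:
    """Material-point BM curve with labels, thickness, cells and history.

    Arrays are indexed by material point, ordered by arc coordinate ``s``
    with ``s[0] == 0``.  The state owns a single seeded RNG from which all
    stochastic draws (divisions, S-phase entry) flow.
    """

    time: float
    s: np.ndarray
    g: np.ndarray
    r: np.ndarray
    w: np.ndarray
    geometry: FollicleGeometry
    bulb_radius: float
    turnover: TurnoverProfile | None = None
    strain: StrainProfile | None = None
    division: DivisionModel | None = None
    cells: list[Cell] = field(default_factory=list)
    rng_seed: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    mkikgr_mode: bool = False
    radial_rate: float = 0.0
    history: list[dict] = field(default_factory=list)
    divisions: list[DivisionEvent] = field(default_factory=list)
    s0: np.ndarray | None = None  # material (initial) arc coordinates
    material_boundaries: list | None = None  # region partition at build time
    _next_cell_id: int = 0

    @property
    def total_arclength(self) -> float:
        return float(self.s[-1])

    @property
    def xy(self) -> np.ndarray:
        return layout_xy(self.s, self.bulb_radius, self.geometry.origin)

    @property
    def stalk_length(self) -> float:
        return (self.total_arclength - np.pi * self.bulb_radius) / 2.0

    def copy(self) -> "FollicleState":
        new = replace(
            self,
            s=self.s.copy(), g=self.g.copy(), r=self.r.copy(), w=self.w.copy(),
            cells=[copy.copy(c) for c in self.cells],
            history=list(self.history), divisions=list(self.divisions),
        )
        return new

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "time": self.time,
            "s": self.s.tolist(), "g": self.g.tolist(),
            "r": self.r.tolist(), "w": self.w.tolist(),
            "bulb_radius": self.bulb_radius,
            "geometry": {
                "stalk_length": self.geometry.stalk_length,
                "bulb_radius": self.geometry.bulb_radius,
                "spacing": self.geometry.spacing,
                "junction_band": self.geometry.junction_band,
                "origin": list(self.geometry.origin),
            },
            "rng_seed": self.rng_seed,
            "mkikgr_mode": self.mkikgr_mode,
            "cells": [
                {"id": c.id, "anchor": c.anchor, "slip": c.slip,
                 "state": c.state, "parent": c.parent, "edu": c.edu}
                for c in self.cells
            ],
            "history": self.history,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FollicleState":
        d = json.loads(text)
        geo = FollicleGeometry(
            stalk_length=d["geometry"]["stalk_length"],
            bulb_radius=d["geometry"]["bulb_radius"],
            spacing=d["geometry"]["spacing"],
            junction_band=d["geometry"]["junction_band"],
            origin=tuple(d["geometry"]["origin"]),
        )
        state = cls(
            time=d["time"],
            s=np.asarray(d["s"]), g=np.asarray(d["g"]),
            r=np.asarray(d["r"]), w=np.asarray(d["w"]),
            geometry=geo, bulb_radius=d["bulb_radius"],
            rng_seed=d["rng_seed"], rng=np.random.default_rng(d["rng_seed"]),
            mkikgr_mode=d.get("mkikgr_mode", False),
            history=d.get("history", []),
        )
        state.cells = [
            Cell(id=c["id"], anchor=c["anchor"], slip=c["slip"],
                 state=c["state"], parent=c["parent"], edu=c["edu"])
            for c in d.get("cells", [])
        ]
        state._next_cell_id = 1 + max((c.id for c in state.cells), default=-1)
        return state


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def layout_xy(s: np.ndarray, bulb_radius: float,
              origin: tuple[float, float]) -> np.ndarray:
    """Map arc coordinates to the plane for the canonical U layout.

    Left stalk descends from the origin, the semicircular bulb turns through
    the tip apex, the right stalk ascends back to the junction line.  The
    bulb radius is fixed by the caller; any arclength growth lengthens the
    stalks, i.e. the follicle elongates downward as the tip invades.
    """
    s = np.asarray(s, dtype=float)
    total = s[-1]
    stalk = (total - np.pi * bulb_radius) / 2.0
    if stalk <= 0:
        raise InvalidParameterError("total arclength shorter than the bulb arc")
    xc, y0 = origin
    xy = np.empty((len(s), 2))
    left = s <= stalk
    xy[left, 0] = xc - bulb_radius
    xy[left, 1] = y0 + s[left]
    arc = (s > stalk) & (s <= stalk + np.pi * bulb_radius)
    phi = (s[arc] - stalk) / bulb_radius
    xy[arc, 0] = xc - bulb_radius * np.cos(phi)
    xy[arc, 1] = y0 + stalk + bulb_radius * np.sin(phi)
    right = s > stalk + np.pi * bulb_radius
    xy[right, 0] = xc + bulb_radius
    xy[right, 1] = y0 + stalk - (s[right] - stalk - np.pi * bulb_radius)
    return xy


def region_boundaries(state: FollicleState) -> list[tuple[str, float, float]]:
    """Ordered (label, lo, hi) partition of [0, total_arclength].

    Tip = the semicircular segment between the bend points; each stalk is
    split at the midpoint of its non-junction part into a tip-adjacent lower
    half and a junction-adjacent upper half; a terminal junction band sits
    at each open end.  Boundary points belong to the more tip-ward region
    (half-open intervals).
    """
    total = state.total_arclength
    stalk = state.stalk_length
    jb = state.geometry.junction_band
    m = (jb + stalk) / 2.0
    tip_lo = stalk
    tip_hi = stalk + np.pi * state.bulb_radius
    return [
        ("junction", 0.0, jb),
        ("upper_stalk", jb, m),
        ("lower_stalk", m, tip_lo),
        ("tip", tip_lo, tip_hi),
        ("lower_stalk", tip_hi, total - m),
        ("upper_stalk", total - m, total - jb),
        ("junction", total - jb, total),
    ]


def region_of(state: FollicleState, s: float | np.ndarray) -> str | np.ndarray:
    """Region label at arc coordinate(s) ``s``; tie-break toward the tip."""
    arr = np.atleast_1d(np.asarray(s, dtype=float))
    total = state.total_arclength
    if np.any(arr < -1e-9) or np.any(arr > total + 1e-9):
        raise RangeError(f"arc coordinate outside [0, {total:.3f}]")
    bounds = region_boundaries(state)
    tip_hi = bounds[3][2]
    out = np.empty(arr.shape, dtype=object)
    for lab, lo, hi in bounds:
        if hi <= tip_hi:  # left side + tip: [lo, hi) except tip closes at hi
            mask = (arr >= lo) & (arr < hi)
            if lab == "tip":
                mask |= np.isclose(arr, hi)
        else:  # right side: (lo, hi] -- boundary goes to the tip-ward region
            mask = (arr > lo) & (arr <= hi)
        out[mask] = lab
    out[np.isclose(arr, total)] = "junction"
    out[np.isclose(arr, 0.0)] = "junction"
    if np.isscalar(s) or np.ndim(s) == 0:
        return str(out[0])
    return out


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def build_follicle(
    geometry: FollicleGeometry | None = None,
    turnover: TurnoverProfile | None = None,
    strain: StrainProfile | None = None,
    division: DivisionModel | None = None,
    seed: int = 0,
    thickness: ThicknessProfile | float = 1.0,
    n_cells: int = 0,
    mkikgr_mode: bool = False,
    radial_rate: float = 0.0,
) -> FollicleState:
    """Build the initial U-shaped BM with g = 1, r = 0 everywhere.

    ``thickness`` is either a constant Gaussian sigma (um) or a
    :class:`ThicknessProfile`.  ``n_cells`` basal cells are placed at
    uniformly spaced arc anchors (deterministic placement; stochasticity
    enters only through the state's RNG during dynamics).
    """
    geometry = geometry or FollicleGeometry()
    total = 2 * geometry.stalk_length + np.pi * geometry.bulb_radius
    n = int(np.ceil(total / geometry.spacing)) + 1
    s = np.linspace(0.0, total, n)
    state = FollicleState(
        time=0.0,
        s=s,
        g=np.ones(n),
        r=np.zeros(n),
        w=np.ones(n),
        geometry=geometry,
        bulb_radius=geometry.bulb_radius,
        turnover=turnover,
        strain=strain,
        division=division,
        rng_seed=int(seed),
        rng=np.random.default_rng(int(seed)),
        mkikgr_mode=mkikgr_mode,
        radial_rate=radial_rate,
    )
    state.s0 = s.copy()
    state.material_boundaries = region_boundaries(state)
    if isinstance(thickness, RegionProfile):
        state.w = np.asarray(thickness(state, s), dtype=float)
    else:
        if thickness <= 0:
            raise InvalidParameterError("thickness sigma must be > 0")
        state.w = np.full(n, float(thickness))
    if n_cells:
        anchors = np.linspace(0.0, total, n_cells + 2)[1:-1]
        state.cells = [Cell(id=i, anchor=float(a)) for i, a in enumerate(anchors)]
        state._next_cell_id = n_cells
    return state


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def step_dynamics(state: FollicleState, dt: float) -> FollicleState:
    """Advance the state by ``dt`` minutes (dt <= 1 for stability).

    Per step: (a) segment lengths scale by exp(eps(s_mid) dt) and the curve
    is re-laid along the updated U; (b) labels follow the exact one-step
    solution of dg/dt = k(1-g-r), dr/dt = -kr with k frozen at the current
    position; (c) cells advect with their material neighborhood plus slip;
    (d) divisions and S-phase entries are drawn from the state's RNG.
    """
    if dt > 1.0 + 1e-12:
        raise StepSizeError("dt must be <= 1 minute")
    if dt <= 0:
        raise StepSizeError("dt must be positive")
    new = state.copy()

    s_old = state.s
    s_mat = state.s0 if state.s0 is not None else s_old
    # (a) growth (strain is a material field: evaluated at initial coords)
    if state.strain is not None:
        mid_mat = 0.5 * (s_mat[:-1] + s_mat[1:])
        eps = state.strain(state, mid_mat)
        ds = np.diff(s_old) * np.exp(eps * dt)
        new.s = np.concatenate([[0.0], np.cumsum(ds)])
    if state.radial_rate:
        new.bulb_radius = state.bulb_radius * float(np.exp(state.radial_rate * dt))

    # (b) turnover (exact one-step update; see module docstring)
    if state.turnover is not None:
        k = state.turnover(state, s_mat)
        decay = np.exp(-k * dt)
        b = 1.0 - state.g - state.r
        b_new = (b + k * state.r * dt) * decay
        r_new = state.r * decay
        new.g = np.clip(1.0 - b_new - r_new, 0.0, 1.0)
        new.r = np.clip(r_new, 0.0, 1.0)

    # (c) cell advection
    total_new = new.s[-1]
    for c in new.cells:
        a = float(np.interp(c.anchor, s_old, new.s)) + c.slip * dt
        c.anchor = min(max(a, 0.0), total_new)

    new.time = state.time + dt

    # (d) stochastic cell cycle, in stable cell order
    if state.division is not None and new.cells:
        dm = state.division
        rng = new.rng
        born: list[Cell] = []
        for c in new.cells:
            reg = region_of(new, c.anchor)
            if c.state == "S_phase" and new.time >= c.s_phase_until:
                c.state = "interphase"
            if c.state == "interphase" and dm.s_phase_rates:
                p_s = dm.s_phase_rates.get(reg, 0.0) * dt / 60.0
                if p_s > 0 and rng.random() < p_s:
                    c.state = "S_phase"
                    c.s_phase_until = new.time + dm.s_phase_duration
            p_div = dm.rates.get(reg, 0.0) * dt / 60.0
            if p_div > 0 and rng.random() < p_div:
                theta = _draw_angle(dm, rng)
                ev, daughter = _divide(new, c, theta, dm.daughter_separation, rng)
                new.divisions.append(ev)
                born.append(daughter)
        new.cells.extend(born)
    return new


def _draw_angle(dm: DivisionModel, rng: np.random.Generator) -> float:
    classes = list(ANGLE_CLASSES)
    probs = np.array([dm.angle_mixture.get(c, 0.0) for c in classes])
    cls = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    lo, hi = ANGLE_CLASSES[cls]
    return float(rng.uniform(lo, hi))


def _divide(state: FollicleState, mother: Cell, theta_deg: float,
            separation: float, rng: np.random.Generator
            ) -> tuple[DivisionEvent, Cell]:
    """Place daughter centroids at +-separation/2 along the division axis."""
    tangent = _tangent_at(state, mother.anchor)
    normal = np.array([-tangent[1], tangent[0]])
    th = np.deg2rad(theta_deg)
    axis = np.cos(th) * tangent + np.sin(th) * normal
    center = layout_xy(np.array([0.0, mother.anchor, state.total_arclength]),
                       state.bulb_radius, state.geometry.origin)[1]
    da = center + 0.5 * separation * axis
    db = center - 0.5 * separation * axis
    ev = DivisionEvent(time=state.time, mother_id=mother.id,
                       daughter_a=(float(da[0]), float(da[1])),
                       daughter_b=(float(db[0]), float(db[1])),
                       s=float(mother.anchor))
    anchor_b = mother.anchor - np.cos(th) * separation / 2.0
    anchor_b = min(max(anchor_b, 0.0), state.total_arclength)
    mother.anchor = min(max(mother.anchor + np.cos(th) * separation / 2.0, 0.0),
                        state.total_arclength)
    daughter = Cell(id=state._next_cell_id, anchor=float(anchor_b),
                    slip=mother.slip, parent=mother.id)
    state._next_cell_id += 1
    return ev, daughter


def _tangent_at(state: FollicleState, s: float, half: float = 2.0) -> np.ndarray:
    """Unit tangent by central difference over +-`half` um of arc."""
    total = state.total_arclength
    s0 = max(s - half, 0.0)
    s1 = min(s + half, total)
    pts = layout_xy(np.array([0.0, s0, s1, total]), state.bulb_radius,
                    state.geometry.origin)
    d = pts[2] - pts[1]
    n = np.linalg.norm(d)
    if n == 0:
        raise RangeError("degenerate tangent window")
    return d / n


def run_dynamics(state: FollicleState, duration: float, dt: float = 1.0
                 ) -> FollicleState:
    """Step ``state`` forward by ``duration`` minutes in dt-sized steps."""
    t_end = state.time + duration
    while state.time < t_end - 1e-9:
        step = min(dt, t_end - state.time)
        state = step_dynamics(state, step)
    return state


# --------------------------------------------------------------------------
# optical events
# --------------------------------------------------------------------------

def _roi_mask(state: FollicleState, roi) -> np.ndarray:
    """Material-point mask for an ROI.

    ROI forms: ``(lo, hi)`` arc interval (um); a list of such intervals; or
    ``{"rect": (x0, y0, x1, y1)}`` in physical micrometres.
    """
    if isinstance(roi, dict) and "rect" in roi:
        x0, y0, x1, y1 = roi["rect"]
        xy = state.xy
        return ((xy[:, 0] >= min(x0, x1)) & (xy[:, 0] <= max(x0, x1))
                & (xy[:, 1] >= min(y0, y1)) & (xy[:, 1] <= max(y0, y1)))
    intervals = roi
    if len(roi) == 2 and np.isscalar(roi[0]):
        intervals = [roi]
    mask = np.zeros(len(state.s), dtype=bool)
    for lo, hi in intervals:
        mask |= (state.s >= lo) & (state.s <= hi)
    return mask


def apply_bleach(state: FollicleState, roi, efficiency: float = 1.0
                 ) -> FollicleState:
    """Photobleach labeled protein inside the ROI: g,r *= (1 - efficiency)."""
    if not (0.0 <= efficiency <= 1.0):
        raise InvalidParameterError("efficiency must be in [0, 1]")
    mask = _roi_mask(state, roi)
    if not mask.any():
        warnings.warn("bleach ROI does not overlap the BM curve; state unchanged")
        return state
    new = state.copy()
    new.g[mask] *= (1.0 - efficiency)
    new.r[mask] *= (1.0 - efficiency)
    new.history.append({"time": state.time, "kind": "bleach",
                        "roi": _roi_json(roi), "efficiency": efficiency})
    return new


def apply_photoconversion(state: FollicleState, roi, efficiency: float = 1.0
                          ) -> FollicleState:
    """Convert green pool to red inside the ROI (mKikGR mode only)."""
    if not state.mkikgr_mode:
        raise InvalidParameterError("photoconversion requires mkikgr_mode")
    if not (0.0 <= efficiency <= 1.0):
        raise InvalidParameterError("efficiency must be in [0, 1]")
    mask = _roi_mask(state, roi)
    if not mask.any():
        warnings.warn("conversion ROI does not overlap the BM curve; state unchanged")
        return state
    new = state.copy()
    transferred = new.g[mask] * efficiency
    new.g[mask] -= transferred
    new.r[mask] += transferred
    new.history.append({"time": state.time, "kind": "convert",
                        "roi": _roi_json(roi), "efficiency": efficiency})
    return new


def _roi_json(roi):
    if isinstance(roi, dict):
        return {"rect": [float(v) for v in roi["rect"]]}
    if len(roi) == 2 and np.isscalar(roi[0]):
        return [[float(roi[0]), float(roi[1])]]
    return [[float(lo), float(hi)] for lo, hi in roi]
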