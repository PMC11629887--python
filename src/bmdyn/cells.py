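"""Cell-level quantification: division angles, frequency, EdU fractions.

Division orientation follows the standard convention for epithelial basal
progenitors: the acute angle theta between the line connecting the two
daughter centroids and the local BM tangent, folded into [0, 90] degrees.
Classes: horizontal (theta < 30), oblique (30 <= theta <= 60),
perpendicular (theta > 60).  Cell tracks are consumed as tables; automated
cell segmentation is deliberately out of scope (the simulator emits
ground-truth tracks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ProximityError, RangeError
from .follicle import DivisionEvent, FollicleState, region_of, run_dynamics
from .frap import CenterlineTrace


@dataclass
class AngleClassification:
    theta: float          # degrees in [0, 90]
    cls: str              # horizontal | oblique | perpendicular


def classify_angle(theta: float) -> AngleClassification:
    """Class membership; the 30 and 60 degree boundaries are oblique."""
    if not (0.0 <= theta <= 90.0):
        raise RangeError("theta must be in [0, 90] degrees")
    if theta < 30.0:
        cls = "horizontal"
    elif theta > 60.0:
        cls = "perpendicular"
    else:
        cls = "oblique"
    return AngleClassification(theta=float(theta), cls=cls)


def division_angle(event: DivisionEvent, trace: CenterlineTrace,
                   max_distance: float = 15.0,
                   tangent_half: float = 2.0) -> AngleClassification:
    """Daughter-allocation angle of one division relative to the BM.

    The BM tangent is estimated by central difference over +-``tangent_half``
    um of arc at the trace point nearest the daughter midpoint.
    """
    a = np.asarray(event.daughter_a, dtype=float)
    b = np.asarray(event.daughter_b, dtype=float)
    if np.allclose(a, b):
        raise RangeError("daughter centroids must be distinct")
    mid = 0.5 * (a + b)
    dist, idx = cKDTree(trace.xy).query(mid)
    if dist > max_distance:
        raise ProximityError(
            f"division {dist:.1f} um from the BM (limit {max_distance})")
    s0 = trace.arc[idx]
    lo = np.interp(max(s0 - tangent_half, trace.arc[0]), trace.arc,
                   np.arange(len(trace.arc)))
    hi = np.interp(min(s0 + tangent_half, trace.arc[-1]), trace.arc,
                   np.arange(len(trace.arc)))
    p_lo = np.array([np.interp(lo, np.arange(len(trace.arc)), trace.xy[:, 0]),
                     np.interp(lo, np.arange(len(trace.arc)), trace.xy[:, 1])])
    p_hi = np.array([np.interp(hi, np.arange(len(trace.arc)), trace.xy[:, 0]),
                     np.interp(hi, np.arange(len(trace.arc)), trace.xy[:, 1])])
    tangent = p_hi - p_lo
    tn = np.linalg.norm(tangent)
    if tn == 0:
        raise RangeError("degenerate BM tangent")
    tangent /= tn
    d = b - a
    d /= np.linalg.norm(d)
    cosang = abs(float(np.dot(d, tangent)))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return classify_angle(min(theta, 90.0))


def angle_distribution(events: list[DivisionEvent], trace: CenterlineTrace,
                       **kwargs) -> dict:
    """Class proportions (percent, 1 decimal) plus the raw theta list."""
    if not events:
        raise RangeError("need at least one division event")
    thetas = []
    classes = []
    for ev in events:
        ac = division_angle(ev, trace, **kwargs)
        thetas.append(ac.theta)
        classes.append(ac.cls)
    n = len(classes)
    props = {c: round(100.0 * classes.count(c) / n, 1)
             for c in ("horizontal", "oblique", "perpendicular")}
    return {"proportions_pct": props, "thetas": thetas, "n": n}


def division_frequency(n_divisions: int, n_cells: int, duration_h: float
                       ) -> float:
    """Divisions per basal cell per hour over the imaging window."""
    if duration_h <= 0:
        raise RangeError("duration must be positive")
    if n_cells == 0:
        return float("nan")
    return n_divisions / (n_cells * duration_h)


def division_frequency_from_tracks(tracks: pd.DataFrame,
                                   divisions: list[DivisionEvent] | int,
                                   duration_h: float) -> float:
    """Frequency from a track table (basal cells = unique initial cell ids)."""
    n_cells = tracks.loc[tracks["t_min"] == tracks["t_min"].min(),
                         "cell_id"].nunique()
    n_div = divisions if isinstance(divisions, int) else len(divisions)
    return division_frequency(n_div, n_cells, duration_h)


# --------------------------------------------------------------------------
# proliferation (EdU)
# --------------------------------------------------------------------------

def edu_fraction_by_region(cells: pd.DataFrame,
                           label_col: str = "edu") -> pd.DataFrame:
    """Per-region percent of labeled basal cells.

    ``cells`` needs columns ``region`` and the boolean ``label_col``; empty
    regions get a NaN fraction (undefined flag) rather than an error.
    """
    if "region" not in cells.columns:
        raise RangeError("every cell must carry a region assignment")
    grouped = cells.groupby("region", sort=True)[label_col].agg(
        labeled="sum", basal_total="count")
    grouped["fraction_pct"] = np.where(
        grouped["basal_total"] > 0,
        100.0 * grouped["labeled"] / grouped["basal_total"], np.nan)
    grouped["labeled"] = grouped["labeled"].astype(int)
    return grouped.reset_index()


def simulate_edu_assay(state: FollicleState, window_min: float = 120.0,
                       dt: float = 1.0) -> pd.DataFrame:
    """EdU-style labeling: flag cells in S phase during the labeling window.

    Steps the state's own dynamics for ``window_min`` minutes; any cell that
    is in S phase at any step is EdU-labeled.  Returns the cell table
    (cell_id, region, edu) at the end of the window.
    """
    labeled: set[int] = set()
    t_end = state.time + window_min
    while state.time < t_end - 1e-9:
        state = run_dynamics(state, min(dt, t_end - state.time), dt=dt)
        labeled |= {c.id for c in state.cells if c.state == "S_phase"}
    rows = [{"cell_id": c.id, "region": region_of(state, c.anchor),
             "edu": c.id in labeled} for c in state.cells]
    return pd.DataFrame(rows)


def tracks_table(states_with_times: list[tuple[float, FollicleState]]
                 ) -> pd.DataFrame:
    """Tidy cell-track table (cell_id, t_min, x_um, y_um, state, region)."""
    from .follicle import layout_xy

    rows = []
    for t, st in states_with_times:
        for c in st.cells:
            xy = layout_xy(np.array([0.0, c.anchor, st.total_arclength]),
                           st.bulb_radius, st.geometry.origin)[1]
            rows.append({"cell_id": c.id, "t_min": t, "x_um": xy[0],
                         "y_um": xy[1], "state": c.state,
                         "region": region_of(st, c.anchor)})
    return pd.DataFrame(rows)
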