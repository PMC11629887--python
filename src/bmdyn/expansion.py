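"""Bleached-edge fiducial tracking, BM length change, thickness, displacement.

Photobleached stripes on the BM act as material landmarks: the half-height
crossings between bright (labeled) and dark (bleached) plateaus of the
centerline intensity profile localize the stripe edges to sub-pixel
precision.  Compartments delimited by consecutive stripes are tracked
across frames (and across re-bleach rounds, which re-draw the stripes along
the advected edges), giving per-compartment length time courses and hence
percent expansion.  Thickness follows the area-over-long-axis convention;
the displacement decomposition splits cell motion into the BM-expansion
contribution and the residual (active) part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    EdgeCountError,
    EdgeLostError,
    GapError,
    MeasureError,
    RangeError,
    TieError,
)
from .frap import CenterlineTrace, sample_bm_intensity
from .imaging import EventLog, GroundTruthManifest, ImageSeries


@dataclass
class BleachEdge:
    """One bright/dark boundary on the trace."""

    position: float            # arc um on the trace
    frame_index: int
    polarity: str              # "falling": bright->dark with increasing arc
    parent_event: str = ""


@dataclass
class CompartmentTrack:
    """Per-frame edge pair and length of one BM compartment."""

    region: str
    times: np.ndarray                 # minutes
    upper_edges: np.ndarray           # arc um (tip-ward smaller index side)
    lower_edges: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower_edges <= self.upper_edges):
            raise RangeError("lower edge must exceed upper edge at every frame")

    @property
    def lengths(self) -> np.ndarray:
        return self.lower_edges - self.upper_edges


@dataclass
class DisplacementRecord:
    """Reference-edge, cell, and lower-edge arc positions over time."""

    times: np.ndarray
    reference_edge: np.ndarray
    cell_position: np.ndarray
    lower_edge: np.ndarray

    @property
    def cell_displacement_pct(self) -> float:
        d = self.cell_position - self.reference_edge
        return 100.0 * (d[-1] - d[0]) / d[0]

    @property
    def bm_expansion_pct(self) -> float:
        d = self.lower_edge - self.reference_edge
        return 100.0 * (d[-1] - d[0]) / d[0]


# --------------------------------------------------------------------------
# edge detection
# --------------------------------------------------------------------------

def intensity_profile(image: np.ndarray, trace: CenterlineTrace,
                      pixel_size: float = 0.5, halfwidth_px: float = 2.0,
                      spacing: float = 0.25, smooth_sigma: float = 0.5,
                      agg: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Centerline intensity vs arc length.

    Z-stacks are averaged plane-wise first (the three-plane averaging of
    the imaging protocol).  ``agg`` selects the per-station statistic over
    the perpendicular band: ``"mean"`` (default; scales the profile by a
    constant cross-section factor, so half-height crossings are unbiased
    and noise is averaged down) or ``"max"`` (ridge peak).  Samples are
    lightly smoothed along the arc first.
    """
    arcs = np.arange(trace.arc[0], trace.arc[-1] - 1e-9, spacing)
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=0)
    pts = np.column_stack([np.interp(arcs, trace.arc, trace.xy[:, 0]),
                           np.interp(arcs, trace.arc, trace.xy[:, 1])])
    tang = np.gradient(pts, axis=0)
    nrm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang /= np.where(nrm == 0, 1, nrm)
    perp = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = (np.arange(-halfwidth_px, halfwidth_px + 1e-9, 0.5) * pixel_size
               if halfwidth_px > 0 else np.array([0.0]))
    sample_xy = pts[:, None, :] + offsets[None, :, None] * perp[:, None, :]
    rows = sample_xy[..., 1] / pixel_size - 0.5
    cols = sample_xy[..., 0] / pixel_size - 0.5
    v = ndimage.map_coordinates(img, [rows.ravel(), cols.ravel()],
                                order=1, mode="nearest").reshape(rows.shape)
    if smooth_sigma > 0 and len(arcs) > 1:
        v = ndimage.gaussian_filter1d(v, smooth_sigma / spacing, axis=0,
                                      mode="nearest")
    vals = v.max(axis=1) if agg == "max" else v.mean(axis=1)
    return arcs, vals


def detect_bleach_edges(arc: np.ndarray, intensity: np.ndarray,
                        expected_count: int | None = None,
                        smooth_sigma: float = 1.0,
                        contrast_limit: float = 0.8,
                        extra_sigma: float = 0.4,
                        frame_index: int = 0) -> list[BleachEdge]:
    """Half-height edge localization on a centerline intensity profile.

    The profile is Gaussian-smoothed (``smooth_sigma`` in um), dark
    intervals are segmented against the local bright plateaus, and each
    edge position is the linear-interpolated crossing of the mid level
    between the flanking bright and dark plateaus.  A dark/bright plateau
    ratio above ``contrast_limit`` means the fiducial has recovered too far
    to localize (signal for a re-bleach).
    """
    arc = np.asarray(arc, dtype=float)
    y = np.asarray(intensity, dtype=float)
    ds = float(np.median(np.diff(arc)))
    sig = max(smooth_sigma / ds, 1e-6)
    ys = ndimage.gaussian_filter1d(y, sigma=sig)
    bright = float(np.percentile(ys, 80))
    dark_mask = ys < bright * contrast_limit
    edges: list[BleachEdge] = []
    idx = np.flatnonzero(dark_mask)
    if len(idx) == 0:
        raise EdgeLostError("no bleached interval with sufficient contrast")
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        i0, i1 = run[0], run[-1]
        margin = max(int(round(2.0 * smooth_sigma / ds)), 1)
        pad = max(int(round(5.0 / ds)), 2)
        left = ys[max(i0 - pad - margin, 0):max(i0 - margin, 0)]
        right = ys[i1 + 1 + margin:i1 + 1 + margin + pad]
        bl = float(np.median(left)) if len(left) else bright
        br = float(np.median(right)) if len(right) else bright
        # per-side minima: turnover gradients can tilt the dark floor
        half = max((i1 - i0 + 1) // 2, 1)
        im_l = i0 + int(np.argmin(ys[i0:i0 + half]))
        im_r = i1 + 1 - half + int(np.argmin(ys[i1 + 1 - half:i1 + 1]))
        min_l = float(ys[im_l])
        min_r = float(ys[im_r])
        # a stripe narrower than ~4 sigma never reaches its dark plateau
        # after smoothing; correct the observed depth by the erf factor of
        # the stripe width so the 50% level refers to the true plateaus
        lvl_l = 0.5 * (bl + min_l)
        lvl_r = 0.5 * (br + min_r)
        p_l = _cross_down(arc, ys, im_l, lvl_l) if len(left) else None
        p_r = _cross_up(arc, ys, im_r, lvl_r) if len(right) else None
        dark_l, dark_r = min_l, min_r
        if p_l is not None and p_r is not None:
            # A stripe only a few sigma wide never reaches its dark plateau
            # after smoothing, and turnover gradients tilt its floor.  Sample
            # the floor just inside each crossing and de-attenuate by the
            # two-edge erf factor, so the 50% level refers to the true local
            # plateau; iterate once to refine the crossings.
            sig = float(np.hypot(smooth_sigma, extra_sigma))
            for _ in range(2):
                width = max(p_r - p_l, ds)
                off = min(1.2 * sig, 0.5 * width)
                x_l, x_r = p_l + off, p_r - off
                f_l = float(np.interp(x_l, arc, ys))
                f_r = float(np.interp(x_r, arc, ys))
                att_l = max(_phi((x_l - p_l) / sig)
                            + _phi((p_r - x_l) / sig) - 1.0, 0.2)
                att_r = max(_phi((x_r - p_l) / sig)
                            + _phi((p_r - x_r) / sig) - 1.0, 0.2)
                dark_l = bl - (bl - f_l) / att_l
                dark_r = br - (br - f_r) / att_r
                if x_r - x_l > 0.5:
                    # extrapolate the tilted floor to the crossings
                    tilt = (dark_r - dark_l) / (x_r - x_l)
                    dark_l, dark_r = (dark_l + tilt * (p_l - x_l),
                                      dark_r + tilt * (p_r - x_r))
                lvl_l = max(0.5 * (bl + dark_l), ys[im_l] + 1e-9)
                lvl_r = max(0.5 * (br + dark_r), ys[im_r] + 1e-9)
                p_l = _cross_down(arc, ys, im_l, lvl_l)
                p_r = _cross_up(arc, ys, im_r, lvl_r)
        if max(dark_l, 0.0) / max(bl, br, 1e-12) > contrast_limit:
            continue
        if p_l is not None:
            edges.append(BleachEdge(position=p_l, frame_index=frame_index,
                                    polarity="falling"))
        if p_r is not None:
            edges.append(BleachEdge(position=p_r, frame_index=frame_index,
                                    polarity="rising"))
    if not edges:
        raise EdgeLostError("bleached-edge contrast too low (needs re-bleach)")
    edges.sort(key=lambda e: e.position)
    if expected_count is not None and len(edges) != expected_count:
        raise EdgeCountError(
            f"expected {expected_count} edges, found {len(edges)}")
    return edges


def _phi(z: float) -> float:
    """Standard normal CDF."""
    from math import erf, sqrt

    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def _cross_down(arc, ys, start, level):
    """Walk left from inside the dark region to the bright side and return
    the interpolated crossing of ``level`` on the falling flank."""
    if ys[start] >= level:
        return float(arc[start])
    i = start
    while i > 0 and ys[i] < level:
        i -= 1
    if ys[i] == ys[i + 1]:
        return float(arc[i])
    f = (ys[i] - level) / (ys[i] - ys[i + 1])
    return float(arc[i] + f * (arc[i + 1] - arc[i]))


def _cross_up(arc, ys, start, level):
    if ys[start] >= level:
        return float(arc[start])
    i = start
    n = len(ys)
    while i < n - 1 and ys[i] < level:
        i += 1
    if ys[i] == ys[i - 1]:
        return float(arc[i])
    f = (level - ys[i - 1]) / (ys[i] - ys[i - 1])
    return float(arc[i - 1] + f * (arc[i] - arc[i - 1]))


# --------------------------------------------------------------------------
# compartment tracking
# --------------------------------------------------------------------------

def track_compartments(series: ImageSeries, event_log: EventLog,
                       traces: list[CenterlineTrace],
                       manifest: GroundTruthManifest | None = None,
                       match_tolerance: float = 6.0,
                       halfwidth_px: float = 2.0,
                       smooth_sigma: float = 0.5) -> list[CompartmentTrack]:
    """Track BM compartments delimited by bleached stripes across a series.

    The initial (multi-stripe) bleach event defines the compartments: the
    unbleached intervals between consecutive stripes.  Edges are detected
    per frame and matched to the previous frame's positions by nearest arc
    position with matching polarity; re-bleach events re-seed the expected
    positions (identity carried by interval overlap, since re-drawn ROIs
    follow the moved edges).  Compartment labels come from the manifest's
    region boundaries at the first post-bleach frame when available.
    """
    initial = next(r for r in event_log.records if r["kind"] == "bleach")
    t0 = initial["time"]
    times = np.asarray(series.timestamps, dtype=float)
    post = np.flatnonzero(times >= t0)
    if len(post) == 0:
        raise GapError("no frames after the initial bleach")
    stripes = sorted((float(lo), float(hi)) for lo, hi in initial["roi"])
    n_comp = len(stripes) - 1
    if n_comp < 1:
        raise GapError("need at least two stripes to delimit a compartment")
    px = series.config.pixel_size

    # expected inner-edge positions: rising edge of stripe i, falling of i+1
    expected = []
    for i in range(n_comp):
        expected.append([stripes[i][1], stripes[i + 1][0]])

    labels = []
    if manifest is not None:
        bounds = manifest.frames[post[0]]["region_boundaries"]
        for i in range(n_comp):
            mid = 0.5 * (expected[i][0] + expected[i][1])
            lab = next((b[0] for b in bounds if b[1] <= mid <= b[2]), "")
            labels.append(lab)
    else:
        labels = [f"compartment_{i}" for i in range(n_comp)]

    rows_u = np.empty((n_comp, len(post)))
    rows_l = np.empty((n_comp, len(post)))
    for col, fi in enumerate(post):
        arc, prof = intensity_profile(series.frames[fi], traces[fi],
                                      pixel_size=px, halfwidth_px=halfwidth_px,
                                      smooth_sigma=0.25)
        edges = detect_bleach_edges(arc, prof, smooth_sigma=smooth_sigma,
                                    frame_index=int(fi))
        rising = [e.position for e in edges if e.polarity == "rising"]
        falling = [e.position for e in edges if e.polarity == "falling"]
        for ci in range(n_comp):
            up = _match(expected[ci][0], rising, match_tolerance)
            lo = _match(expected[ci][1], falling, match_tolerance)
            rows_u[ci, col] = up
            rows_l[ci, col] = lo
            expected[ci] = [up, lo]
    return [
        CompartmentTrack(region=labels[ci], times=times[post],
                         upper_edges=rows_u[ci], lower_edges=rows_l[ci])
        for ci in range(n_comp)
    ]


def _match(target: float, candidates: list[float], tol: float) -> float:
    near = [c for c in candidates if abs(c - target) <= tol]
    if not near:
        raise EdgeLostError(f"no edge within {tol} um of {target:.2f}")
    if len(near) > 1:
        near.sort(key=lambda c: abs(c - target))
        if abs(near[1] - target) - abs(near[0] - target) < 0.5:
            raise TieError(f"ambiguous edge match near {target:.2f}: {near}")
    return min(near, key=lambda c: abs(c - target))


def percent_length_change(track: CompartmentTrack, t0: float, t1: float,
                          time_tolerance: float = 1e-6) -> float:
    """100 * (L(t1) - L(t0)) / L(t0) for one compartment."""
    if t0 >= t1:
        raise RangeError("t0 must precede t1")

    def _frame(t):
        d = np.abs(track.times - t)
        i = int(np.argmin(d))
        if d[i] > max(time_tolerance, 1e-6):
            raise GapError(f"no frame at t={t} (nearest {track.times[i]})")
        return i

    l0 = track.lengths[_frame(t0)]
    l1 = track.lengths[_frame(t1)]
    return float(100.0 * (l1 - l0) / l0)


# --------------------------------------------------------------------------
# thickness
# --------------------------------------------------------------------------

def measure_thickness(image: np.ndarray, trace: CenterlineTrace,
                      window: tuple[float, float], pixel_size: float = 0.5,
                      threshold_frac: float = 0.5,
                      perp_halfwidth: float = 6.0) -> float:
    """Area-over-long-axis BM thickness within an arc window of 5-10 um.

    The supra-threshold cross-section width (threshold relative to the
    *local* per-station peak, so label gradients and gain do not bias it)
    is found by interpolated crossings and averaged along the window:
    equivalently, supra-threshold area divided by the window arc length.
    """
    lo, hi = window
    if not (5.0 - 1e-9 <= hi - lo <= 10.0 + 1e-9):
        raise RangeError("window length must be 5-10 um")
    if not (trace.arc[0] - 1e-6 <= lo < hi <= trace.arc[-1] + 1e-6):
        raise RangeError("window outside trace span")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=0)
    arcs = np.arange(lo, hi + 1e-9, 0.25)
    pts = np.column_stack([np.interp(arcs, trace.arc, trace.xy[:, 0]),
                           np.interp(arcs, trace.arc, trace.xy[:, 1])])
    tang = np.gradient(pts, axis=0)
    nrm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang /= np.where(nrm == 0, 1, nrm)
    perp = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-perp_halfwidth, perp_halfwidth + 1e-9, 0.1)
    sample_xy = pts[:, None, :] + offsets[None, :, None] * perp[:, None, :]
    rows = sample_xy[..., 1] / pixel_size - 0.5
    cols = sample_xy[..., 0] / pixel_size - 0.5
    prof = ndimage.map_coordinates(img, [rows.ravel(), cols.ravel()],
                                   order=1, mode="nearest").reshape(rows.shape)
    bg = float(np.median(img))
    widths = []
    for p in prof:
        peak = p.max() - bg
        if peak <= 0:
            continue
        level = bg + threshold_frac * peak
        above = p >= level
        if not above.any():
            continue
        i0, i1 = np.flatnonzero(above)[[0, -1]]
        w_lo = offsets[i0] if i0 == 0 else _interp_cross(offsets, p, i0 - 1, i0,
                                                         level)
        w_hi = offsets[i1] if i1 == len(p) - 1 else _interp_cross(
            offsets, p, i1 + 1, i1, level)
        widths.append(w_hi - w_lo)
    if not widths:
        raise MeasureError("no supra-threshold pixels in the window")
    return float(np.mean(widths))


def _interp_cross(x, y, i_out, i_in, level):
    """Crossing of `level` between an outside sample and an inside sample."""
    if y[i_in] == y[i_out]:
        return float(x[i_in])
    f = (level - y[i_out]) / (y[i_in] - y[i_out])
    return float(x[i_out] + f * (x[i_in] - x[i_out]))


# --------------------------------------------------------------------------
# displacement decomposition
# --------------------------------------------------------------------------

def decompose_displacement(record: DisplacementRecord | None = None, *,
                           cell_pct: float | None = None,
                           bm_pct: float | None = None) -> dict:
    """Split normalized cell displacement into BM contribution and residual.

    ``bm_contribution_pct`` = 100 * (BM expansion % / cell displacement %);
    ``residual_points`` = cell displacement % - BM expansion % (percentage
    points of relative motion not explained by riding the expanding BM).
    Zero cell displacement yields an undefined flag, not an exception.
    """
    if record is not None:
        cell_pct = record.cell_displacement_pct
        bm_pct = record.bm_expansion_pct
    if cell_pct is None or bm_pct is None:
        raise ValueError("need a record or both cell_pct and bm_pct")
    if cell_pct == 0:
        return {"bm_contribution_pct": float("nan"),
                "residual_points": float("nan"), "defined": False}
    return {"bm_contribution_pct": 100.0 * bm_pct / cell_pct,
            "residual_points": cell_pct - bm_pct, "defined": True}


def displacement_record_from_tracks(times: np.ndarray, ref_edge: np.ndarray,
                                    cell_pos: np.ndarray,
                                    lower_edge: np.ndarray
                                    ) -> DisplacementRecord:
    return DisplacementRecord(times=np.asarray(times, dtype=float),
                              reference_edge=np.asarray(ref_edge, dtype=float),
                              cell_position=np.asarray(cell_pos, dtype=float),
                              lower_edge=np.asarray(lower_edge, dtype=float))
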