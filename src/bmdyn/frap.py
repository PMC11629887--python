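"""FRAP quantification: centerline tracing, normalization, linear fitting.

The pipeline mirrors the manual analysis of BM photobleaching movies: a
line is traced along the BM, mean intensity over the bleached interval is
read per frame (per-pixel maxima across a perpendicular band, averaged
along the line, averaged over z planes), divided by the pre-bleach mean
after background subtraction, and the post-bleach recovery is fitted by
simple linear regression.  Recovery in this system reflects incorporation
of new protein rather than diffusion, so it has no plateau on the imaging
timescale and a line is the stable fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .errors import FitError, ProtocolError, RangeError, TraceError
from .imaging import EventLog, GroundTruthManifest, ImageSeries


@dataclass
class CenterlineTrace:
    """Ordered polyline along the BM with cumulative arc length (um)."""

    xy: np.ndarray            # (M, 2) physical um
    arc: np.ndarray           # (M,) cumulative um, arc[0] = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc) <= 0):
            raise TraceError("trace arc length must be strictly increasing")


@dataclass
class RecoveryCurve:
    """Normalized FRAP trajectory (pre-bleach mean == 1)."""

    times: np.ndarray          # minutes post-bleach (pre-bleach negative)
    values: np.ndarray
    region: str = ""
    roi_id: str = ""

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.times >= 0]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.times >= 0]

    def value_at(self, t: float) -> float:
        """Linear interpolation of the post-bleach curve at time t."""
        return float(np.interp(t, self.post_times, self.post_values))


@dataclass
class RecoveryFit:
    """Ordinary least-squares line through the post-bleach recovery."""

    slope: float               # per minute
    intercept: float
    window: tuple[float, float]
    stderr: float = float("nan")
    t50: float = float("nan")
    t50_defined: bool = False
    t50_extrapolated: bool = False

    def recovery_at(self, t: float) -> float:
        return self.intercept + self.slope * t


# --------------------------------------------------------------------------
# tracing
# --------------------------------------------------------------------------

def trace_centerline(image: np.ndarray, seed_point: tuple[float, float],
                     pixel_size: float = 0.5, threshold_frac: float = 0.5,
                     manifest: GroundTruthManifest | None = None,
                     frame_index: int = 0) -> CenterlineTrace:
    """Trace the BM ridge through ``seed_point`` (physical um).

    Threshold at ``threshold_frac`` of the local peak, skeletonize, and walk
    the connected skeleton path containing the seed.  When a ground-truth
    manifest is supplied the true polyline is returned instead (test mode).
    """
    if manifest is not None:
        s, xy = manifest.frame_polyline(frame_index)
        return CenterlineTrace(xy=xy, arc=s - s[0], frame_index=frame_index)

    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # z-stack: trace on the mean plane
        img = img.mean(axis=0)
    sj, si = seed_point[0] / pixel_size, seed_point[1] / pixel_size
    i0, j0 = int(round(si)), int(round(sj))
    if not (0 <= i0 < img.shape[0] and 0 <= j0 < img.shape[1]):
        raise TraceError("seed point outside the image")
    win = img[max(i0 - 10, 0):i0 + 11, max(j0 - 10, 0):j0 + 11]
    local_peak = win.max()
    background = np.median(img)
    if local_peak <= background + 0.05 * (img.max() - background + 1e-12):
        raise TraceError("no ridge at the seed point")
    mask = img > background + threshold_frac * (local_peak - background)
    skel = skeletonize(mask)
    pix = np.argwhere(skel)
    if len(pix) == 0:
        raise TraceError("no ridge at the seed point")
    d2 = (pix[:, 0] - si) ** 2 + (pix[:, 1] - sj) ** 2
    if d2.min() > 25:  # seed more than 5 px from any ridge pixel
        raise TraceError("no ridge at the seed point")
    path = _walk_skeleton(skel, tuple(pix[np.argmin(d2)]))
    xy = np.column_stack([(path[:, 1] + 0.5) * pixel_size,
                          (path[:, 0] + 0.5) * pixel_size])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return CenterlineTrace(xy=xy, arc=arc, frame_index=frame_index)


def _walk_skeleton(skel: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Ordered pixel path of the skeleton component containing ``seed``."""
    offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)]

    def neighbors(p):
        return [(p[0] + di, p[1] + dj) for di, dj in offs
                if 0 <= p[0] + di < skel.shape[0]
                and 0 <= p[1] + dj < skel.shape[1]
                and skel[p[0] + di, p[1] + dj]]

    # collect the connected component
    comp = {seed}
    frontier = [seed]
    while frontier:
        p = frontier.pop()
        for q in neighbors(p):
            if q not in comp:
                comp.add(q)
                frontier.append(q)
    # start from an endpoint (fewest in-component neighbors)
    start = min(comp, key=lambda p: len([q for q in neighbors(p) if q in comp]))
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in neighbors(cur) if q in comp and q not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation for a smoother path
        nxt.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
        cur = nxt[0]
        path.append(cur)
        visited.add(cur)
    return np.asarray(path)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def sample_bm_intensity(image: np.ndarray, trace: CenterlineTrace,
                        interval: tuple[float, float], halfwidth_px: float = 2.0,
                        pixel_size: float = 0.5,
                        station_spacing: float = 0.25,
                        smooth_sigma: float = 1.0) -> float:
    """Mean BM intensity over an arc interval of the trace.

    At stations along the interval, pixels are sampled (bilinear) along the
    perpendicular over +-``halfwidth_px``; the per-station maximum is taken
    and averaged along the interval.  Samples are Gaussian-smoothed along
    the arc (``smooth_sigma`` um) before the per-station max so that the
    max does not systematically ride the noise at low signal.  For a
    (Z, H, W) stack, the per-plane line means are averaged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return float(np.mean([
            sample_bm_intensity(pl, trace, interval, halfwidth_px, pixel_size,
                                station_spacing, smooth_sigma) for pl in img]))
    lo, hi = interval
    if not (trace.arc[0] - 1e-6 <= lo < hi <= trace.arc[-1] + 1e-6):
        raise RangeError("interval outside trace span")
    arcs = np.arange(lo, hi + 1e-9, station_spacing)
    pts = np.column_stack([np.interp(arcs, trace.arc, trace.xy[:, 0]),
                           np.interp(arcs, trace.arc, trace.xy[:, 1])])
    # tangents by finite difference of the station sequence
    tang = np.gradient(pts, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.where(norm == 0, 1, norm)
    perp = np.column_stack([-tang[:, 1], tang[:, 0]])
    if halfwidth_px > 0:
        offsets = np.arange(-halfwidth_px, halfwidth_px + 1e-9, 0.5) * pixel_size
    else:
        offsets = np.array([0.0])
    # sample grid: stations x offsets
    sample_xy = pts[:, None, :] + offsets[None, :, None] * perp[:, None, :]
    rows = sample_xy[..., 1] / pixel_size - 0.5
    cols = sample_xy[..., 0] / pixel_size - 0.5
    vals = ndimage.map_coordinates(img, [rows.ravel(), cols.ravel()],
                                   order=1, mode="nearest")
    vals = vals.reshape(rows.shape)
    if smooth_sigma > 0 and len(arcs) > 1:
        vals = ndimage.gaussian_filter1d(vals, smooth_sigma / station_spacing,
                                         axis=0, mode="nearest")
    return float(vals.max(axis=1).mean())


def estimate_background(image: np.ndarray, trace: CenterlineTrace,
                        pixel_size: float = 0.5, margin_px: float = 3.0) -> float:
    """Median intensity of pixels farther than ``margin_px`` from the trace."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=0)
    h, w = img.shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([(jj.ravel() + 0.5) * pixel_size,
                           (ii.ravel() + 0.5) * pixel_size])
    dist, _ = cKDTree(trace.xy).query(pts)
    far = dist > margin_px * pixel_size
    return float(np.median(img.ravel()[far]))


# --------------------------------------------------------------------------
# normalization and fitting
# --------------------------------------------------------------------------

def normalize_recovery(series: ImageSeries, event_log: EventLog, roi_id: str,
                       traces: list[CenterlineTrace],
                       manifest: GroundTruthManifest | None = None,
                       intervals: list[tuple[float, float]] | None = None,
                       halfwidth_px: float = 2.0,
                       subtract_background: bool = True,
                       region: str = "") -> RecoveryCurve:
    """Normalized recovery of a bleached interval across a series.

    The bleached material interval per frame comes from ``intervals`` (one
    per frame) or, in test mode, from the ground-truth manifest.  Values are
    frame means over the interval, background-subtracted, divided by the
    mean over all pre-bleach frames.
    """
    event = event_log.by_id(roi_id)
    t_event = event["time"]
    times = np.asarray(series.timestamps, dtype=float)
    pre = times < t_event
    if not pre.any():
        raise ProtocolError("no pre-bleach frames before the event")
    if intervals is None:
        if manifest is None:
            raise ProtocolError("need per-frame intervals or a manifest")
        intervals = []
        for i in range(len(times)):
            ivs = manifest.interval_at(roi_id, i)
            if ivs is None or len(ivs) == 0:
                # before the event the material interval equals the event roi
                ivs = [tuple(event["roi"][0])] if len(event["roi"]) else []
            lo = min(iv[0] for iv in ivs)
            hi = max(iv[1] for iv in ivs)
            intervals.append((lo, hi))
    px = series.config.pixel_size
    raw = np.empty(len(times))
    bg = np.zeros(len(times))
    for i, t in enumerate(times):
        frame = series.frames[i]
        raw[i] = sample_bm_intensity(frame, traces[i], intervals[i],
                                     halfwidth_px=halfwidth_px, pixel_size=px)
        if subtract_background:
            bg[i] = estimate_background(frame, traces[i], pixel_size=px)
    corrected = raw - bg
    baseline = corrected[pre].mean()
    if baseline <= 0:
        raise ProtocolError("non-positive pre-bleach baseline")
    return RecoveryCurve(times=times - t_event, values=corrected / baseline,
                         region=region, roi_id=roi_id)


def fit_recovery(curve: RecoveryCurve,
                 window: tuple[float, float] | None = None) -> RecoveryFit:
    """Simple linear regression of normalized intensity on post-bleach time.

    t50 (time to reach 0.5) comes from inverting the fitted line; it is
    flagged undefined for non-positive slopes and flagged extrapolated when
    it falls outside the observed post-bleach time span.
    """
    t = curve.post_times
    v = curve.post_values
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    else:
        window = (float(t[0]), float(t[-1])) if len(t) else (0.0, 0.0)
    if len(t) < 3:
        raise FitError("need at least 3 post-bleach points")
    res = stats.linregress(t, v)
    fit = RecoveryFit(slope=float(res.slope), intercept=float(res.intercept),
                      window=(float(window[0]), float(window[1])),
                      stderr=float(res.stderr))
    if fit.slope > 0:
        fit.t50 = (0.5 - fit.intercept) / fit.slope
        fit.t50_defined = True
        fit.t50_extrapolated = not (t[0] <= fit.t50 <= t[-1])
    return fit


def fit_recovery_exponential(curve: RecoveryCurve) -> dict:
    """Optional cross-check: 1 - (1 - v0) exp(-k t) fit (never the headline)."""
    from scipy.optimize import curve_fit

    t = curve.post_times
    v = curve.post_values
    if len(t) < 3:
        raise FitError("need at least 3 post-bleach points")

    def model(t, k, v0):
        return 1.0 - (1.0 - v0) * np.exp(-k * t)

    popt, _ = curve_fit(model, t, v, p0=[1e-3, float(v[0])],
                        bounds=([0, -0.5], [1.0, 1.0]), maxfev=10000)
    return {"k": float(popt[0]), "v0": float(popt[1])}
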