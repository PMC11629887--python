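"""Render follicle states into noisy time-lapse image series.

The BM curve is drawn with a Gaussian cross-section whose sigma is the local
material thickness ``w`` and whose *peak* amplitude is proportional to the
local labeled fraction (``g`` for the green channel, ``r`` for the red
photoconverted channel), so thickness changes do not masquerade as label
changes.  Noise is shot noise (Poisson at a configurable photon scale) plus
Gaussian read noise; both off when their parameters are zero.

Coordinates: image origin top-left, row-major, y increases downward;
physical units are micrometres via the configured pixel size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.spatial import cKDTree

from .errors import ConfigError, InvalidParameterError, SeriesParseError
from .follicle import (
    FollicleState,
    apply_bleach,
    apply_photoconversion,
    region_boundaries,
    step_dynamics,
)


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition parameters for the synthetic microscope."""

    pixel_size: float = 0.5      # um/px
    frame_interval: float = 10.0  # minutes
    image_shape: tuple[int, int] = (192, 192)
    photon_scale: float = 100.0   # photons per intensity unit; 0 = no shot noise
    read_sigma: float = 0.01      # Gaussian read noise sd; 0 = off
    background: float = 0.1
    amplitude: float = 1.0        # peak intensity of a fully labeled BM
    z_planes: int = 1             # 1 or 3 identical planes (noise independent)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidParameterError("pixel_size and frame_interval must be > 0")


@dataclass
class ImageSeries:
    """Frames indexed (t, z), timestamps in minutes, plus the config used."""

    frames: np.ndarray            # (T, Z, H, W) float32, BM (green) channel
    timestamps: np.ndarray        # (T,) minutes
    config: ImagingConfig
    channels: dict = field(default_factory=dict)  # optional: "red", "cells"

    def __post_init__(self) -> None:
        if len(self.timestamps) != self.frames.shape[0]:
            raise InvalidParameterError("frame count must match timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")

    def frame(self, t_index: int, z: int = 0) -> np.ndarray:
        return self.frames[t_index, z]


@dataclass
class EventLog:
    """Ordered photobleach/photoconversion records."""

    records: list[dict] = field(default_factory=list)

    def add(self, *, time: float, kind: str, roi, efficiency: float,
            event_id: str) -> None:
        self.records.append({"id": event_id, "time": float(time), "kind": kind,
                             "roi": [[float(a), float(b)] for a, b in roi],
                             "efficiency": float(efficiency)})

    def by_id(self, event_id: str) -> dict:
        for rec in self.records:
            if rec["id"] == event_id:
                return rec
        raise KeyError(event_id)

    def to_json(self) -> str:
        return json.dumps({"records": self.records})

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        return cls(records=json.loads(text)["records"])


@dataclass
class GroundTruthManifest:
    """Per-frame ground truth emitted alongside the rendered series."""

    frames: list[dict] = field(default_factory=list)
    bleach_intervals: dict = field(default_factory=dict)  # event id -> per-frame
    divisions: list[dict] = field(default_factory=list)
    profiles: dict = field(default_factory=dict)

    def frame_polyline(self, t_index: int) -> tuple[np.ndarray, np.ndarray]:
        fr = self.frames[t_index]
        return np.asarray(fr["s"]), np.asarray(fr["xy"])

    def interval_at(self, event_id: str, t_index: int
                    ) -> list[tuple[float, float]] | None:
        """Advected material arc interval(s) of a bleach event at a frame.

        None for frames acquired before the event fired.
        """
        ivs = self.bleach_intervals[event_id][t_index]
        if ivs is None:
            return None
        return [tuple(iv) for iv in ivs]

    def to_json(self) -> str:
        return json.dumps({"frames": self.frames,
                           "bleach_intervals": self.bleach_intervals,
                           "divisions": self.divisions,
                           "profiles": self.profiles})


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_frame(state: FollicleState, config: ImagingConfig,
                 rng: np.random.Generator | None = None,
                 channel: str = "green") -> np.ndarray:
    """Render one (H, W) frame of the BM channel.

    Intensity = background + amplitude * fraction(nearest material point) *
    exp(-d^2 / (2 w^2)), with d the distance to the curve.  Shot/read noise
    are applied when enabled and an RNG is given.
    """
    h, w_px = config.image_shape
    px = config.pixel_size
    xy = state.xy
    if (xy[:, 0].min() < 0 or xy[:, 1].min() < 0
            or xy[:, 0].max() > w_px * px or xy[:, 1].max() > h * px):
        warnings.warn("BM curve extends outside the field of view; clipping")
    frac = state.g if channel == "green" else state.r
    # densify the curve so point-distance approximates true curve distance
    fine_s = np.arange(0.0, state.s[-1] + 1e-9, 0.1)
    fine_xy = np.column_stack([np.interp(fine_s, state.s, xy[:, 0]),
                               np.interp(fine_s, state.s, xy[:, 1])])
    fine_frac = np.interp(fine_s, state.s, frac)
    fine_w = np.interp(fine_s, state.s, state.w)
    tree = cKDTree(fine_xy)
    jj, ii = np.meshgrid(np.arange(w_px), np.arange(h))
    pts = np.column_stack([(jj.ravel() + 0.5) * px, (ii.ravel() + 0.5) * px])
    cutoff = 5.0 * float(state.w.max()) + 2.0 * px
    dist, idx = tree.query(pts, distance_upper_bound=cutoff)
    img = np.full(pts.shape[0], config.background)
    hit = np.isfinite(dist)
    near = np.minimum(idx[hit], len(fine_xy) - 1)
    img[hit] += (config.amplitude * fine_frac[near]
                 * np.exp(-dist[hit] ** 2 / (2.0 * fine_w[near] ** 2)))
    img = img.reshape(h, w_px)
    if rng is not None:
        if config.photon_scale > 0:
            img = rng.poisson(np.maximum(img, 0.0) * config.photon_scale
                              ) / config.photon_scale
        if config.read_sigma > 0:
            img = img + rng.normal(0.0, config.read_sigma, size=img.shape)
    return img.astype(np.float64)


def render_cells(state: FollicleState, config: ImagingConfig,
                 radius: float = 2.5, offset: float = 3.0) -> np.ndarray:
    """Crude membrane-marker channel: disks at cell positions.

    Cells sit just inside the BM (offset along the inward normal).  This
    channel exists for visual context; quantification consumes track tables.
    """
    from .follicle import _tangent_at, layout_xy

    h, w_px = config.image_shape
    px = config.pixel_size
    img = np.zeros((h, w_px))
    if not state.cells:
        return img
    jj, ii = np.meshgrid(np.arange(w_px), np.arange(h))
    gx = (jj + 0.5) * px
    gy = (ii + 0.5) * px
    for c in state.cells:
        tangent = _tangent_at(state, c.anchor)
        normal = np.array([-tangent[1], tangent[0]])
        pos = layout_xy(np.array([0.0, c.anchor, state.total_arclength]),
                        state.bulb_radius, state.geometry.origin)[1]
        # inward = toward the bulb axis (negative of outward normal on the U)
        center = pos - offset * normal
        img = np.maximum(img, np.exp(-((gx - center[0]) ** 2 +
                                       (gy - center[1]) ** 2) / (2 * radius ** 2)))
    return img


# --------------------------------------------------------------------------
# experiment driver
# --------------------------------------------------------------------------

def simulate_experiment(scenario) -> tuple[ImageSeries, EventLog, GroundTruthManifest]:
    """Run a scenario: dynamics + optical events + rendering + ground truth.

    Frames are collected every ``scenario.frame_interval`` minutes from
    ``-pre_time`` to ``duration``; events fire at their scheduled times;
    re-bleach rounds re-target the advected material of the initial bleach
    stripes so the fiducial edges stay sharp (one log record per
    compartment, mirroring re-drawn per-compartment ROIs).
    """
    from .scenario import Scenario  # local import to avoid a cycle

    sc: Scenario = scenario
    config = sc.imaging
    state = sc.build_state()
    state.time = -float(sc.pre_time)

    for ev in sc.events:
        if not (0.0 <= ev["time"] <= sc.duration):
            raise ConfigError(f"event at t={ev['time']} outside [0, {sc.duration}]")

    frame_times = np.arange(-float(sc.pre_time), sc.duration + 1e-9,
                            config.frame_interval)
    rebleach_times: list[float] = []
    if sc.rebleach_period:
        t = sc.rebleach_period
        while t < sc.duration - 1e-9:
            rebleach_times.append(float(t))
            t += sc.rebleach_period

    base_rng = np.random.default_rng(sc.seed)
    render_rng = np.random.default_rng(base_rng.integers(2 ** 31))
    state.rng = np.random.default_rng(base_rng.integers(2 ** 31))

    # timeline of actions: (time, order, kind, payload)
    actions = [(float(t), 2, "frame", None) for t in frame_times]
    for i, ev in enumerate(sc.events):
        actions.append((float(ev["time"]), 0, "event", (i, ev)))
    for j, t in enumerate(rebleach_times):
        actions.append((t, 1, "rebleach", j))
    actions.sort(key=lambda a: (a[0], a[1]))

    event_log = EventLog()
    manifest = GroundTruthManifest(profiles=sc.profile_summary())
    stripe_masks: list[np.ndarray] = []   # material masks of initial stripes
    tracked_ids: list[str] = []           # event ids with tracked material
    tracked_masks: dict[str, np.ndarray] = {}
    frames: list[np.ndarray] = []
    timestamps: list[float] = []

    noise_on = config.photon_scale > 0 or config.read_sigma > 0

    for t, _, kind, payload in actions:
        while state.time < t - 1e-9:
            state = step_dynamics(state, min(sc.dt, t - state.time))
        if kind == "event":
            i, ev = payload
            eid = ev.get("id", f"E{i}")
            rois = _resolve_roi(state, ev["roi"])
            if ev["kind"] == "bleach":
                state = apply_bleach(state, rois, ev["efficiency"])
            elif ev["kind"] == "convert":
                state = apply_photoconversion(state, rois, ev["efficiency"])
            else:
                raise ConfigError(f"unknown event kind {ev['kind']!r}")
            event_log.add(time=t, kind=ev["kind"], roi=rois,
                          efficiency=ev["efficiency"], event_id=eid)
            mask = np.zeros(len(state.s), dtype=bool)
            for lo, hi in rois:
                mask |= (state.s >= lo) & (state.s <= hi)
            tracked_ids.append(eid)
            tracked_masks[eid] = mask
            if ev["kind"] == "bleach" and ev.get("stripes"):
                # remember each stripe's material separately for re-bleaching
                for lo, hi in rois:
                    stripe_masks.append((state.s >= lo) & (state.s <= hi))
        elif kind == "rebleach":
            j = payload
            comps = _compartments_from_stripes(state, stripe_masks)
            for ci, (m_up, m_lo) in enumerate(comps):
                rois = (_mask_intervals(state, m_up)
                        + _mask_intervals(state, m_lo))
                state = apply_bleach(state, rois, sc.rebleach_efficiency)
                event_log.add(time=t, kind="bleach", roi=rois,
                              efficiency=sc.rebleach_efficiency,
                              event_id=f"RB{j}C{ci}")
        else:  # frame
            zplanes = [render_frame(state, config,
                                    render_rng if noise_on else None)
                       for _ in range(config.z_planes)]
            frames.append(np.stack(zplanes))
            timestamps.append(t)
            entry = {
                "time": t,
                "s": state.s.tolist(),
                "xy": state.xy.tolist(),
                "g": state.g.tolist(),
                "r": state.r.tolist(),
                "w": state.w.tolist(),
                "region_boundaries": [[lab, lo, hi] for lab, lo, hi
                                      in region_boundaries(state)],
                "cells": [{"id": c.id, "s": c.anchor, "state": c.state,
                           "edu": c.edu} for c in state.cells],
            }
            manifest.frames.append(entry)
            for eid in tracked_ids:
                ivs = _mask_intervals(state, tracked_masks[eid])
                manifest.bleach_intervals.setdefault(eid, {})
                manifest.bleach_intervals[eid][len(frames) - 1] = \
                    [[lo, hi] for lo, hi in ivs]
    # pad interval tracking for frames before each event
    nframes = len(frames)
    for eid in tracked_ids:
        per = manifest.bleach_intervals[eid]
        manifest.bleach_intervals[eid] = [per.get(i) for i in range(nframes)]
    manifest.divisions = [
        {"time": d.time, "mother_id": d.mother_id, "s": d.s,
         "daughter_a": list(d.daughter_a), "daughter_b": list(d.daughter_b)}
        for d in state.divisions
    ]

    series = ImageSeries(frames=np.stack(frames).astype(np.float32),
                         timestamps=np.asarray(timestamps), config=config)
    return series, event_log, manifest


def _resolve_roi(state: FollicleState, roi) -> list[tuple[float, float]]:
    """Normalize a scenario ROI spec into arc intervals on the current state."""
    if isinstance(roi, dict):
        if "arc" in roi:
            return [(float(lo), float(hi)) for lo, hi in roi["arc"]]
        if "center" in roi:  # interval of given length centered at an arc pos
            c, ln = float(roi["center"]), float(roi["length"])
            return [(c - ln / 2, c + ln / 2)]
        raise ConfigError(f"unsupported ROI spec {roi!r}")
    if len(roi) == 2 and np.isscalar(roi[0]):
        return [(float(roi[0]), float(roi[1]))]
    return [(float(lo), float(hi)) for lo, hi in roi]


def _mask_intervals(state: FollicleState, mask: np.ndarray
                    ) -> list[tuple[float, float]]:
    """Arc interval(s) currently spanned by a material-point mask."""
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        out.append((float(state.s[run[0]]), float(state.s[run[-1]])))
    return out


def _compartments_from_stripes(state: FollicleState,
                               stripe_masks: list[np.ndarray]
                               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair consecutive stripes (sorted by arc) into compartment flanks."""
    if len(stripe_masks) < 2:
        return []
    order = np.argsort([state.s[np.flatnonzero(m)].mean() for m in stripe_masks])
    sorted_masks = [stripe_masks[i] for i in order]
    return [(sorted_masks[i], sorted_masks[i + 1])
            for i in range(len(sorted_masks) - 1)]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_series(path: str | Path, series: ImageSeries, seed: int | None = None
                 ) -> None:
    """Write a multi-page TIFF (axes TZYX) plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, series.frames, metadata={"axes": "TZYX"})
    sidecar = {
        "timestamps": [float(t) for t in series.timestamps],
        "config": {**asdict(series.config),
                   "image_shape": list(series.config.image_shape)},
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_series(path: str | Path) -> ImageSeries:
    """Read a series written by :func:`write_series` (lossless round trip)."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise SeriesParseError(f"cannot parse {path.name}: {exc}") from exc
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SeriesParseError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    cfg_d = dict(sidecar["config"])
    cfg_d["image_shape"] = tuple(cfg_d["image_shape"])
    config = ImagingConfig(**cfg_d)
    frames = np.asarray(frames)
    if frames.ndim == 3:  # single z collapsed by the reader
        frames = frames[:, None]
    return ImageSeries(frames=frames, timestamps=np.asarray(sidecar["timestamps"]),
                       config=config)
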