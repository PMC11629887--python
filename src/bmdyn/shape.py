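"""Follicle-level morphometrics: length, bulb width, shape factor.

The shape factor S = L_HF / W_HF (follicle length over maximal bulb width)
summarizes the elongating-cylinder vs widened-bulb distinction: S rises
during normal cylindrical elongation and stalls or falls when elongation
halts while the bulb widens.  The follicle axis is the principal axis of
the outline (reproducible, unlike hand annotation); length is measured
from the junction chord to the apex along that axis, width as the maximal
perpendicular extent within the lower (bulb) half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .errors import MeasureError, RangeError
from .follicle import FollicleState


@dataclass
class ShapeMeasure:
    length: float        # L_HF, um
    width: float         # W_HF, um

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise MeasureError("length and width must be positive")

    @property
    def shape_factor(self) -> float:
        return self.length / self.width


def measure_shape(source: FollicleState | np.ndarray,
                  pixel_size: float = 0.5,
                  threshold_frac: float = 0.5) -> ShapeMeasure:
    """Shape measurement from a state or a BM-channel image.

    For an image, the outline is the largest connected supra-threshold
    component (threshold relative to the max above background),
    morphologically closed.
    """
    if isinstance(source, FollicleState):
        pts = source.xy
    else:
        img = np.asarray(source, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=0)
        bg = float(np.median(img))
        mask = img > bg + threshold_frac * (img.max() - bg)
        mask = morphology.closing(mask, morphology.disk(2))
        lab = measure.label(mask)
        if lab.max() == 0:
            raise MeasureError("no supra-threshold outline")
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        pix = np.argwhere(lab == largest)
        pts = np.column_stack([(pix[:, 1] + 0.5) * pixel_size,
                               (pix[:, 0] + 0.5) * pixel_size])
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]          # principal (long) axis
    proj = centered @ axis
    perp = centered @ np.array([-axis[1], axis[0]])
    # orient the axis so the apex (far from the junction chord) is positive:
    # the junction chord is the end with the two open curve ends
    ends_proj = (np.array([pts[0], pts[-1]]) - pts.mean(axis=0)) @ axis \
        if isinstance(source, FollicleState) else None
    if ends_proj is not None and ends_proj.mean() > 0:
        proj = -proj
        ends_proj = -ends_proj
    if ends_proj is not None:
        length = float(proj.max() - ends_proj.mean())
    else:
        length = float(proj.max() - proj.min())
    lower = proj > 0.5 * (proj.max() + proj.min())
    if not lower.any():
        raise MeasureError("degenerate outline")
    width = float(perp[lower].max() - perp[lower].min())
    if width <= 0:
        raise MeasureError("degenerate outline (zero width)")
    return ShapeMeasure(length=length, width=width)


def shape_timecourse(states: list[FollicleState],
                     times: list[float] | np.ndarray) -> pd.DataFrame:
    """Per-frame shape measures with changes and values normalized to t0."""
    times = np.asarray(times, dtype=float)
    if len(states) < 2:
        raise RangeError("need at least two timepoints")
    if np.any(np.diff(times) <= 0):
        raise RangeError("times must be strictly increasing")
    rows = []
    for t, st in zip(times, states):
        m = measure_shape(st)
        rows.append({"t_min": t, "L_um": m.length, "W_um": m.width,
                     "S": m.shape_factor})
    df = pd.DataFrame(rows)
    for col, d in (("L_um", "dL_um"), ("W_um", "dW_um"), ("S", "dS")):
        df[d] = df[col] - df[col].iloc[0]
        df[col.split("_")[0] + "_norm"] = df[col] / df[col].iloc[0]
    return df
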