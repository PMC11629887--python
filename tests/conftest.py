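import numpy as np
import pytest

import bmdyn as bd


@pytest.fixture(scope="session")
def default_state():
    return bd.build_follicle()


@pytest.fixture(scope="session")
def control_params():
    return bd.load_preset_params("control")


@pytest.fixture()
def straight_trace():
    """A straight horizontal BM trace at y = 16 um, 0..60 um of arc."""
    xs = np.arange(0.0, 60.01, 0.5)
    xy = np.column_stack([xs, np.full_like(xs, 16.0)])
    return bd.CenterlineTrace(xy=xy, arc=xs.copy())


def make_straight_image(shape=(64, 128), pixel_size=0.5, y_um=16.0,
                        sigma=1.0, background=0.1, amplitude=1.0,
                        dark_intervals_um=()):
    """Noise-free image of a straight horizontal BM with optional dark gaps."""
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = (jj + 0.5) * pixel_size
    y = (ii + 0.5) * pixel_size
    amp = np.full(w, amplitude)
    xs = (np.arange(w) + 0.5) * pixel_size
    for lo, hi in dark_intervals_um:
        amp[(xs >= lo) & (xs <= hi)] = 0.0
    img = background + amp[None, :] * np.exp(-(y - y_um) ** 2 / (2 * sigma ** 2))
    return img
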