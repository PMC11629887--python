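"""Tests for bleached-edge detection, compartment tracking, thickness,
and the displacement decomposition."""

import numpy as np
import pytest

import bmdyn as bd
from bmdyn.errors import EdgeLostError, GapError, RangeError
from conftest import make_straight_image


def step_profile(edge_positions, lo=0.1, hi=1.1, span=100.0, ds=0.25):
    """Synthetic bright/dark profile with ideal steps at given positions."""
    s = np.arange(0.0, span, ds)
    y = np.full_like(s, hi)
    dark = False
    for i, pos in enumerate(sorted(edge_positions)):
        if i % 2 == 0:
            y[s >= pos] = lo
        else:
            y[s >= pos] = hi
    return s, y


class TestDetectEdges:
    def test_ideal_step_localized_subpixel(self):
        s, y = step_profile([50.0, 70.0])
        edges = bd.detect_bleach_edges(s, y)
        falling = [e for e in edges if e.polarity == "falling"]
        assert falling[0].position == pytest.approx(50.0, abs=0.25)

    def test_two_intervals_four_alternating_edges(self):
        s, y = step_profile([20.0, 30.0, 60.0, 70.0])
        edges = bd.detect_bleach_edges(s, y, expected_count=4)
        assert [e.polarity for e in edges] == ["falling", "rising"] * 2

    def test_low_contrast_raises_edge_lost(self):
        s = np.arange(0.0, 100.0, 0.25)
        y = np.full_like(s, 1.0)
        y[(s > 40) & (s < 60)] = 0.9  # recovered to 90% of bright
        with pytest.raises(EdgeLostError):
            bd.detect_bleach_edges(s, y)

    def test_edge_tracks_advected_material_within_one_micron(self):
        """After 150 min of tip-rate turnover + growth, the detected edge
        stays within 1 um of the advected material ground truth."""
        sc = bd.expansion_scenario(preset="control", seed=0, duration=150.0,
                                   rebleach_period=None)
        series, log, manifest = bd.simulate_experiment(sc)
        i_last = len(series.timestamps) - 1
        trace = bd.trace_centerline(None, None, manifest=manifest,
                                    frame_index=i_last)
        arc, prof = bd.intensity_profile(series.frames[i_last], trace,
                                         pixel_size=series.config.pixel_size)
        edges = bd.detect_bleach_edges(arc, prof)
        truth = [b for iv in manifest.interval_at("COMPART", i_last)
                 for b in iv]
        for pos in truth:
            assert min(abs(e.position - pos) for e in edges) <= 1.0


class TestTrackCompartments:
    def test_static_bm_zero_length_change(self):
        sc = bd.expansion_scenario(strain={}, preset="control", seed=1)
        sc.strain = None
        tracks = bd.expansion_pipeline(sc)
        for tr in tracks:
            assert abs(bd.percent_length_change(tr, 0.0, 420.0)) < 1.0

    def test_tip_thirty_percent_expansion(self):
        """Tip strain ln(1.3)/420 per min gives +30% +- 3 at 7 h."""
        val = bd.mean_tip_expansion(seeds=[0, 1],
                                    strain={"tip": np.log(1.3) / 420.0})
        assert val == pytest.approx(30.0, abs=3.0)

    def test_mmpi_six_percent_expansion(self):
        val = bd.mean_tip_expansion(seeds=[0, 1], preset="mmpi")
        assert val == pytest.approx(6.0, abs=3.0)

    def test_compartment_edges_are_consistent(self):
        tracks = bd.expansion_pipeline(
            bd.expansion_scenario(preset="control", seed=0))
        assert [t.region for t in tracks] == ["upper_stalk", "lower_stalk",
                                              "tip"]
        for a, b in zip(tracks[:-1], tracks[1:]):
            assert np.all(a.lower_edges < b.upper_edges)  # stripe between
        # additivity: end-to-end distance = compartments + stripe interiors
        span = tracks[-1].lower_edges - tracks[0].upper_edges
        comps = sum(t.lengths for t in tracks)
        gaps = sum(b.upper_edges - a.lower_edges
                   for a, b in zip(tracks[:-1], tracks[1:]))
        assert np.allclose(span, comps + gaps)

    def test_null_expansion_replicates(self):
        """Zero strain: |length change| < 1% in >= 95% of 20 replicates."""
        ok = 0
        n_rep = 20
        for rep in range(n_rep):
            sc = bd.expansion_scenario(preset="control", seed=2000 + rep,
                                       duration=420.0)
            sc.strain = None
            tracks = bd.expansion_pipeline(sc)
            if all(abs(bd.percent_length_change(t, 0.0, 420.0)) < 1.0
                   for t in tracks):
                ok += 1
        assert ok >= int(0.95 * n_rep)


class TestPercentLengthChange:
    def _track(self, lengths, times=None):
        lengths = np.asarray(lengths, dtype=float)
        times = np.asarray(times if times is not None
                           else np.arange(len(lengths)), dtype=float)
        return bd.CompartmentTrack(region="tip", times=times,
                                   upper_edges=np.zeros_like(lengths),
                                   lower_edges=lengths)

    def test_thirty_percent(self):
        assert bd.percent_length_change(self._track([30.0, 39.0]), 0, 1) == \
            pytest.approx(30.0)

    def test_upper_stalk_shrinkage_scale(self):
        assert bd.percent_length_change(self._track([30.0, 29.1]), 0, 1) == \
            pytest.approx(-3.0)

    def test_no_change_is_zero(self):
        assert bd.percent_length_change(self._track([30.0, 30.0]), 0, 1) == 0.0

    def test_missing_frame_raises_gap(self):
        with pytest.raises(GapError):
            bd.percent_length_change(self._track([30.0, 39.0]), 0, 7.0)


@pytest.fixture(scope="module")
def clean_render():
    th = bd.ThicknessProfile({"tip": 1.0, "lower_stalk": 1.0,
                              "upper_stalk": 1.55, "junction": 1.55})
    state = bd.build_follicle(thickness=th)
    cfg = bd.ImagingConfig(photon_scale=0.0, read_sigma=0.0)
    img = bd.render_frame(state, cfg)
    trace = bd.CenterlineTrace(xy=state.xy, arc=state.s)
    return state, img, trace


class TestThickness:

    def test_halfheight_width_of_gaussian_section(self, clean_render):
        state, img, trace = clean_render
        apex = state.total_arclength / 2.0
        t = bd.measure_thickness(img, trace, (apex - 3.75, apex + 3.75))
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma = 1 um
        assert t == pytest.approx(fwhm, rel=0.05)

    def test_junction_fiftyfive_percent_thicker(self, clean_render):
        state, img, trace = clean_render
        apex = state.total_arclength / 2.0
        t_tip = bd.measure_thickness(img, trace, (apex - 3.75, apex + 3.75))
        t_up = bd.measure_thickness(img, trace, (10.25, 17.75))
        assert t_up / t_tip == pytest.approx(1.55, abs=0.05)

    def test_gain_invariance(self, clean_render):
        state, img, trace = clean_render
        w = (10.25, 17.75)
        assert bd.measure_thickness(2.0 * img, trace, w) == \
            pytest.approx(bd.measure_thickness(img, trace, w), abs=1e-9)

    def test_window_length_bounds(self, clean_render):
        state, img, trace = clean_render
        with pytest.raises(RangeError):
            bd.measure_thickness(img, trace, (10.0, 13.0))  # 3 um < 5 um


class TestDecomposeDisplacement:
    def test_lower_stalk_printed_values(self):
        out = bd.decompose_displacement(cell_pct=32.0, bm_pct=22.0)
        assert out["bm_contribution_pct"] == pytest.approx(68.75)
        assert out["residual_points"] == pytest.approx(10.0)

    def test_fully_coupled(self):
        out = bd.decompose_displacement(cell_pct=10.0, bm_pct=10.0)
        assert out["bm_contribution_pct"] == pytest.approx(100.0)
        assert out["residual_points"] == pytest.approx(0.0)

    def test_upper_stalk_scale(self):
        out = bd.decompose_displacement(cell_pct=4.0, bm_pct=-3.0)
        assert out["residual_points"] == pytest.approx(7.0)

    def test_zero_cell_displacement_flagged_not_raised(self):
        out = bd.decompose_displacement(cell_pct=0.0, bm_pct=5.0)
        assert not out["defined"] and np.isnan(out["bm_contribution_pct"])

    def test_slip_detection_recovers_configured_slip(self):
        """A cell slipping at v um/min on a static BM yields a residual equal
        to the slip-induced relative change (within 20% relative)."""
        state = bd.build_follicle(n_cells=0)
        v = 0.02  # um/min toward the tip
        cell = bd.Cell(id=0, anchor=30.0, slip=v)
        state.cells = [cell]
        ref, lower = 20.0, 40.0  # static material landmarks (no strain)
        times, cell_pos = [], []
        T = 420.0
        snap = state
        for t in np.arange(0.0, T + 1, 30.0):
            while snap.time < t - 1e-9:
                snap = bd.step_dynamics(snap, 1.0)
            times.append(t)
            cell_pos.append(snap.cells[0].anchor)
        rec = bd.DisplacementRecord(
            times=np.asarray(times),
            reference_edge=np.full(len(times), ref),
            cell_position=np.asarray(cell_pos),
            lower_edge=np.full(len(times), lower))
        out = bd.decompose_displacement(rec)
        expected = 100.0 * v * T / (30.0 - ref)
        assert out["residual_points"] == pytest.approx(expected, rel=0.2)
        assert out["bm_contribution_pct"] == pytest.approx(0.0, abs=1e-9)
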