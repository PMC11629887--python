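"""Tests for division-angle classification, frequency, and EdU fractions."""

import numpy as np
import pandas as pd
import pytest

import bmdyn as bd
from bmdyn.errors import ProximityError, RangeError
from bmdyn.follicle import DivisionEvent


@pytest.fixture(scope="module")
def flat_trace():
    """Horizontal BM trace: tangent along x everywhere."""
    xs = np.arange(0.0, 60.01, 0.5)
    return bd.CenterlineTrace(xy=np.column_stack([xs, np.full_like(xs, 30.0)]),
                              arc=xs.copy())


def event(a, b):
    return DivisionEvent(time=0.0, mother_id=0, daughter_a=a, daughter_b=b,
                         s=0.0)


class TestDivisionAngle:
    @pytest.mark.parametrize("a,b,theta,cls", [
        ((20.0, 30.0), (22.0, 30.0), 0.0, "horizontal"),
        ((20.0, 29.0), (20.0, 31.0), 90.0, "perpendicular"),
        ((20.0, 30.0), (21.0, 31.0), 45.0, "oblique"),
    ])
    def test_axis_geometry(self, flat_trace, a, b, theta, cls):
        ac = bd.division_angle(event(a, b), flat_trace)
        assert ac.theta == pytest.approx(theta, abs=1e-6)
        assert ac.cls == cls

    def test_daughter_order_symmetry(self, flat_trace):
        ac1 = bd.division_angle(event((20.0, 30.0), (21.5, 31.0)), flat_trace)
        ac2 = bd.division_angle(event((21.5, 31.0), (20.0, 30.0)), flat_trace)
        assert ac1.theta == pytest.approx(ac2.theta)

    def test_reflection_across_tangent_symmetry(self, flat_trace):
        ac1 = bd.division_angle(event((20.0, 30.0), (21.0, 31.4)), flat_trace)
        ac2 = bd.division_angle(event((20.0, 30.0), (21.0, 28.6)), flat_trace)
        assert ac1.theta == pytest.approx(ac2.theta, abs=1e-6)

    def test_far_event_raises_proximity(self, flat_trace):
        with pytest.raises(ProximityError):
            bd.division_angle(event((20.0, 50.0), (22.0, 50.0)), flat_trace)

    def test_identical_daughters_rejected(self, flat_trace):
        with pytest.raises(RangeError):
            bd.division_angle(event((20.0, 30.0), (20.0, 30.0)), flat_trace)

    def test_on_curved_tip(self):
        """Tangent follows the bulb: a division axis along the local tangent
        at the tip apex is horizontal even though it is vertical in x-y."""
        state = bd.build_follicle()
        trace = bd.CenterlineTrace(xy=state.xy, arc=state.s)
        apex_idx = int(np.argmax(state.xy[:, 1]))
        x0, y0 = state.xy[apex_idx]
        ac = bd.division_angle(event((x0 - 1.0, y0), (x0 + 1.0, y0)), trace)
        assert ac.cls == "horizontal"
        ac2 = bd.division_angle(event((x0, y0 - 2.0), (x0, y0)), trace)
        assert ac2.cls == "perpendicular"


class TestClassifierBoundaries:
    @pytest.mark.parametrize("theta,cls", [
        (29.999, "horizontal"), (30.0, "oblique"), (45.0, "oblique"),
        (60.0, "oblique"), (60.001, "perpendicular"), (0.0, "horizontal"),
        (90.0, "perpendicular"),
    ])
    def test_boundary_conformance(self, theta, cls):
        assert bd.classify_angle(theta).cls == cls


class TestAngleDistribution:
    def _events_with_angles(self, thetas, trace):
        evs = []
        for th in thetas:
            r = np.deg2rad(th)
            evs.append(event((20.0, 30.0),
                             (20.0 + 2 * np.cos(r), 30.0 + 2 * np.sin(r))))
        return evs

    def test_control_mixture_percentages(self, flat_trace):
        thetas = [10.0] * 24 + [45.0] * 5 + [80.0] * 19  # 48 divisions
        out = bd.angle_distribution(
            self._events_with_angles(thetas, flat_trace), flat_trace)
        assert out["proportions_pct"] == {"horizontal": 50.0, "oblique": 10.4,
                                          "perpendicular": 39.6}

    def test_mmpi_mixture_percentages(self, flat_trace):
        thetas = [10.0] * 5 + [45.0] * 4 + [80.0] * 27  # 36 divisions
        out = bd.angle_distribution(
            self._events_with_angles(thetas, flat_trace), flat_trace)
        assert out["proportions_pct"] == {"horizontal": 13.9, "oblique": 11.1,
                                          "perpendicular": 75.0}

    def test_all_oblique(self, flat_trace):
        out = bd.angle_distribution(
            self._events_with_angles([45.0] * 7, flat_trace), flat_trace)
        assert out["proportions_pct"] == {"horizontal": 0.0, "oblique": 100.0,
                                          "perpendicular": 0.0}

    def test_proportions_sum_to_100(self, flat_trace):
        rng = np.random.default_rng(0)
        thetas = rng.uniform(0, 90, 33)
        out = bd.angle_distribution(
            self._events_with_angles(thetas, flat_trace), flat_trace)
        assert sum(out["proportions_pct"].values()) == pytest.approx(100.0,
                                                                     abs=0.2)


class TestDivisionFrequency:
    def test_imaging_window_arithmetic(self):
        # 5 divisions among 10 basal cells over the 9.5-h imaging window
        assert bd.division_frequency(5, 10, 9.5) == pytest.approx(0.0526,
                                                                  abs=1e-4)

    def test_zero_divisions(self):
        assert bd.division_frequency(0, 10, 9.5) == 0.0

    def test_doubling_duration_halves_rate(self):
        assert bd.division_frequency(5, 10, 19.0) == \
            pytest.approx(bd.division_frequency(5, 10, 9.5) / 2)

    def test_zero_cells_undefined(self):
        assert np.isnan(bd.division_frequency(5, 0, 9.5))


class TestEduFractions:
    def test_simple_fractions(self):
        cells = pd.DataFrame({
            "region": ["tip"] * 10 + ["upper_stalk"] * 4,
            "edu": [True] * 8 + [False] * 2 + [False] * 4,
        })
        out = bd.edu_fraction_by_region(cells)
        tip = out.loc[out.region == "tip"].iloc[0]
        assert tip.labeled == 8 and tip.basal_total == 10
        assert tip.fraction_pct == pytest.approx(80.0)
        up = out.loc[out.region == "upper_stalk"].iloc[0]
        assert up.fraction_pct == pytest.approx(0.0)

    def test_simulated_gradient_ordering(self, control_params):
        """S-phase rate gradient tip > lower > upper reproduces the same
        ordering of EdU fractions in >= 95% of replicates."""
        dv = control_params["division"]
        ok = 0
        n_rep = 10
        for rep in range(n_rep):
            dm = bd.DivisionModel(rates={}, s_phase_rates=dv["s_phase_rates"])
            state = bd.build_follicle(division=dm, n_cells=200,
                                      seed=500 + rep)
            table = bd.simulate_edu_assay(state, window_min=120.0)
            f = bd.edu_fraction_by_region(table).set_index("region")[
                "fraction_pct"]
            if f["tip"] > f["lower_stalk"] > f["upper_stalk"]:
                ok += 1
        assert ok >= int(0.95 * n_rep)


def test_simulated_division_angles_match_mixture(control_params):
    """End-to-end: simulator divisions classified by the pipeline reproduce
    the configured angle mixture."""
    dv = control_params["division"]
    dm = bd.DivisionModel(rates={r: 0.6 for r in bd.REGIONS},
                          angle_mixture=dv["angle_mixture"])
    state = bd.build_follicle(division=dm, n_cells=150, seed=8)
    state = bd.run_dynamics(state, 120.0)
    trace = bd.CenterlineTrace(xy=state.xy, arc=state.s)
    out = bd.angle_distribution(state.divisions, trace)
    assert out["n"] >= 100
    assert out["proportions_pct"]["horizontal"] == pytest.approx(50.0, abs=12)
    assert out["proportions_pct"]["perpendicular"] == pytest.approx(39.6,
                                                                    abs=12)
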