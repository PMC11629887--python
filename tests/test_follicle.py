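"""Unit and property tests for the follicle growth/turnover model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bmdyn as bd
from bmdyn.errors import InvalidParameterError, RangeError, StepSizeError


class TestBuild:
    def test_arclength_is_two_stalks_plus_semicircle(self):
        state = bd.build_follicle(bd.FollicleGeometry(stalk_length=40.0,
                                                      bulb_radius=15.0))
        assert state.total_arclength == pytest.approx(80.0 + np.pi * 15.0)

    def test_initial_labels_fully_green(self, default_state):
        assert default_state.g.min() == default_state.g.max() == 1.0
        assert default_state.r.max() == 0.0

    def test_points_ordered_and_anchored(self, default_state):
        s = default_state.s
        assert s[0] == 0.0
        assert np.all(np.diff(s) > 0)
        assert default_state.total_arclength == s[-1]

    def test_same_seed_identical(self):
        a = bd.build_follicle(seed=7, n_cells=20)
        b = bd.build_follicle(seed=7, n_cells=20)
        assert np.array_equal(a.s, b.s) and np.array_equal(a.xy, b.xy)
        assert [c.anchor for c in a.cells] == [c.anchor for c in b.cells]

    @pytest.mark.parametrize("kw", [{"stalk_length": -1.0},
                                    {"bulb_radius": 0.0},
                                    {"spacing": 0.8}])
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            bd.FollicleGeometry(**kw)


class TestRegions:
    @pytest.mark.parametrize("s,expected", [
        (0.0, "junction"),
        (30.0, "lower_stalk"),       # tip-adjacent half of the 5-40 stalk
        (10.0, "upper_stalk"),
        ((80.0 + np.pi * 15.0) / 2.0, "tip"),  # apex by symmetry
    ])
    def test_examples(self, default_state, s, expected):
        assert bd.region_of(default_state, s) == expected

    def test_partition_matches_bruteforce(self, default_state):
        """Every grid point lands in the region the boundary table implies."""
        bounds = bd.region_boundaries(default_state)
        total = default_state.total_arclength
        grid = np.linspace(0.0, total, 997)
        for s in grid:
            # brute force: last interval whose [lo, hi] contains s, preferring
            # the more tip-ward side at shared boundaries
            hits = [(lab, lo, hi) for lab, lo, hi in bounds if lo <= s <= hi]
            apex = total / 2.0
            hits.sort(key=lambda b: abs(0.5 * (b[1] + b[2]) - apex))
            assert bd.region_of(default_state, s) == hits[0][0]

    def test_outside_domain_raises(self, default_state):
        with pytest.raises(RangeError):
            bd.region_of(default_state, default_state.total_arclength + 1.0)

    def test_boundaries_tile_domain(self, default_state):
        bounds = bd.region_boundaries(default_state)
        assert bounds[0][1] == 0.0
        assert bounds[-1][2] == pytest.approx(default_state.total_arclength)
        for (_, _, hi), (_, lo, _) in zip(bounds[:-1], bounds[1:]):
            assert hi == pytest.approx(lo)


class TestDynamics:
    def test_half_life_reaches_half_recovery(self):
        k = np.log(2) / 205.0
        state = bd.build_follicle(turnover=bd.TurnoverProfile.uniform(k))
        state.g[:] = 0.0
        state = bd.run_dynamics(state, 205.0)
        assert state.g == pytest.approx(0.5, abs=1e-6)

    def test_exponential_growth_oracle(self):
        eps = np.log(1.3) / 420.0
        state = bd.build_follicle(strain=bd.StrainProfile.uniform(eps))
        l0 = state.total_arclength
        state = bd.run_dynamics(state, 420.0)
        assert state.total_arclength / l0 == pytest.approx(1.30, abs=1e-6)

    def test_null_dynamics_is_identity(self, default_state):
        state = bd.build_follicle(turnover=bd.TurnoverProfile.uniform(0.0),
                                  strain=bd.StrainProfile.uniform(0.0))
        out = bd.run_dynamics(state, 30.0)
        assert out.time == pytest.approx(30.0)
        assert np.allclose(out.s, state.s) and np.allclose(out.g, state.g)

    def test_oversized_step_rejected(self, default_state):
        with pytest.raises(StepSizeError):
            bd.step_dynamics(default_state, 2.0)

    def test_multistep_matches_closed_form_with_red_pool(self):
        """Numerical label update vs b(t) = (b0 + k r0 t) e^{-kt} closed form."""
        k = 2.3e-3
        state = bd.build_follicle(turnover=bd.TurnoverProfile.uniform(k),
                                  mkikgr_mode=True)
        state = bd.apply_photoconversion(state, (40.0, 70.0), 0.8)
        g0, r0 = state.g.copy(), state.r.copy()
        T = 137.0
        state = bd.run_dynamics(state, T)
        r_exact = r0 * np.exp(-k * T)
        b_exact = (1 - g0 - r0 + k * r0 * T) * np.exp(-k * T)
        assert np.allclose(state.r, r_exact, atol=1e-6)
        assert np.allclose(state.g, 1 - b_exact - r_exact, atol=1e-6)

    def test_coupled_cell_rides_material(self):
        """slip = 0: a cell glued to a material point stays glued under
        advection, and turnover alone never moves cells."""
        eps = bd.StrainProfile({"tip": 6e-4, "lower_stalk": 3e-4,
                                "upper_stalk": 0.0, "junction": 0.0})
        state = bd.build_follicle(strain=eps, n_cells=10)
        i = 150  # a material point in the growing flank
        state.cells[4].anchor = float(state.s[i])
        state = bd.run_dynamics(state, 180.0)
        assert state.cells[4].anchor == pytest.approx(state.s[i], abs=1e-6)

        quiet = bd.build_follicle(
            turnover=bd.TurnoverProfile.uniform(3e-3), n_cells=10)
        anchors = [c.anchor for c in quiet.cells]
        quiet = bd.run_dynamics(quiet, 120.0)
        assert [c.anchor for c in quiet.cells] == pytest.approx(anchors)

    def test_trajectory_determinism_with_divisions(self, control_params):
        dm = bd.DivisionModel(rates=control_params["division"]["rates"],
                              angle_mixture=control_params["division"]
                              ["angle_mixture"])
        runs = []
        for _ in range(2):
            st = bd.build_follicle(division=dm, n_cells=40, seed=11)
            st = bd.run_dynamics(st, 120.0)
            runs.append(st)
        a, b = runs
        assert np.array_equal(a.s, b.s)
        assert [(c.id, c.anchor) for c in a.cells] == \
            [(c.id, c.anchor) for c in b.cells]
        assert len(a.divisions) == len(b.divisions)


class TestOpticalEvents:
    def test_complete_bleach_confined_to_roi(self, default_state):
        state = bd.apply_bleach(bd.build_follicle(), (50.0, 65.0), 1.0)
        inside = (state.s >= 50.0) & (state.s <= 65.0)
        assert np.all(state.g[inside] == 0.0)
        assert np.all(state.g[~inside] == 1.0)

    def test_zero_efficiency_is_noop(self):
        state = bd.apply_bleach(bd.build_follicle(), (50.0, 65.0), 0.0)
        assert np.all(state.g == 1.0)

    def test_rebleach_idempotent_at_full_efficiency(self):
        state = bd.apply_bleach(bd.build_follicle(), (50.0, 65.0), 1.0)
        again = bd.apply_bleach(state, (50.0, 65.0), 1.0)
        assert np.array_equal(state.g, again.g)

    def test_empty_overlap_warns_and_preserves_state(self):
        state = bd.build_follicle()
        with pytest.warns(UserWarning):
            out = bd.apply_bleach(state, {"rect": (0.0, 0.0, 1.0, 1.0)}, 1.0)
        assert np.all(out.g == 1.0)

    def test_full_conversion_swaps_pools(self):
        state = bd.build_follicle(mkikgr_mode=True)
        state = bd.apply_photoconversion(state, (50.0, 65.0), 1.0)
        inside = (state.s >= 50.0) & (state.s <= 65.0)
        assert np.all(state.g[inside] == 0.0)
        assert np.all(state.r[inside] == 1.0)

    def test_conversion_conserves_total_label(self):
        state = bd.build_follicle(mkikgr_mode=True)
        before = state.g + state.r
        state = bd.apply_photoconversion(state, (30.0, 90.0), 0.6)
        assert np.allclose(state.g + state.r, before)

    def test_conversion_requires_mkikgr_mode(self, default_state):
        with pytest.raises(InvalidParameterError):
            bd.apply_photoconversion(bd.build_follicle(), (50.0, 60.0), 1.0)

    def test_red_pool_replaced_by_green(self):
        """Pulse-chase: converted red decays while green recovers."""
        k = np.log(2) / 205.0
        state = bd.build_follicle(turnover=bd.TurnoverProfile.uniform(k),
                                  mkikgr_mode=True)
        state = bd.apply_photoconversion(state, (50.0, 65.0), 1.0)
        inside = (state.s >= 50.0) & (state.s <= 65.0)
        T = 480.0  # red "almost disappeared during 8-10 h of culture"
        state = bd.run_dynamics(state, T)
        r_expected = np.exp(-k * T)
        g_expected = 1.0 - r_expected - k * T * np.exp(-k * T)
        sel = slice(np.flatnonzero(inside)[2], np.flatnonzero(inside)[-2])
        assert state.r[sel] == pytest.approx(r_expected, abs=1e-6)
        assert state.g[sel] == pytest.approx(g_expected, abs=1e-6)
        assert np.all(state.g[sel] > state.r[sel])  # green replaces red


@settings(max_examples=25, deadline=None, derandomize=True)
@given(eff1=st.floats(0, 1), eff2=st.floats(0, 1),
       lo=st.floats(5, 60), span=st.floats(1, 40),
       minutes=st.integers(0, 120))
def test_label_bounds_invariant(eff1, eff2, lo, span, minutes):
    """0 <= g, r and g + r <= 1 after any event/step sequence."""
    k = 3e-3
    state = bd.build_follicle(turnover=bd.TurnoverProfile.uniform(k),
                              mkikgr_mode=True)
    state = bd.apply_photoconversion(state, (lo, lo + span), eff1)
    state = bd.run_dynamics(state, float(minutes))
    state = bd.apply_bleach(state, (lo + span / 2, lo + span * 1.5), eff2)
    state = bd.run_dynamics(state, 30.0)
    assert np.all(state.g >= 0) and np.all(state.r >= 0)
    assert np.all(state.g + state.r <= 1 + 1e-12)


def test_json_roundtrip():
    state = bd.build_follicle(n_cells=5, seed=3)
    state = bd.apply_bleach(state, (50.0, 60.0), 0.5)
    back = bd.FollicleState.from_json(state.to_json())
    assert np.allclose(back.s, state.s) and np.allclose(back.g, state.g)
    assert [c.id for c in back.cells] == [c.id for c in state.cells]
    assert back.history == state.history
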