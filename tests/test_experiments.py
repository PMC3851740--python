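"""The three transport simulations: gradients, allocation, height sweep."""

import numpy as np
import pytest

from treevasc import TreeSpec, PINE
from treevasc.experiments import (DEFAULT_SETTINGS, SimulationSettings,
                                  calibrated_model, optimize_phloem_allocation,
                                  run_axial_profile_experiment,
                                  run_height_sweep)
from treevasc.transport import RHO_W_G, solve_steady_state

FAST = SimulationSettings(n_nodes=200)


@pytest.fixture(scope="module")
def axial_sw(pine_sw2cm):
    return run_axial_profile_experiment(pine_sw2cm, "root", settings=FAST)


@pytest.fixture(scope="module")
def axial_nohw(pine_nohw):
    return run_axial_profile_experiment(pine_nohw, "root", settings=FAST)


def test_calibration_reaches_the_target_turgor_difference(pine_sw2cm):
    model = calibrated_model(pine_sw2cm, FAST)
    st = model.solve("root")
    assert st.turgor_difference == pytest.approx(FAST.dP_target, abs=2e-3)


def test_phloem_turgor_drop_concentrates_toward_the_base(axial_sw):
    assert axial_sw.basal_half_turgor_fraction > 0.5


def test_no_heartwood_shifts_the_drop_further_basal(axial_sw, axial_nohw):
    assert axial_nohw.basal_half_turgor_fraction \
        > axial_sw.basal_half_turgor_fraction


def test_xylem_potential_drops_steeply_near_the_apex(axial_sw):
    assert axial_sw.apical_psi_gradient > axial_sw.basal_psi_gradient


def test_normalized_profiles_are_base_relative(axial_sw):
    df = axial_sw.normalized_profiles()
    assert df["P_p_rel"].iloc[-1] == pytest.approx(1.0)
    assert df["c_rel"].iloc[-1] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def result_root(pine_sw2cm):
    return optimize_phloem_allocation(pine_sw2cm, "root", settings=FAST)


class TestAllocation:

    def test_phloem_volume_is_conserved_across_theta(self, result_root):
        assert result_root.volume_residual < 1e-3

    def test_coarse_grid_brackets_the_refined_minimizer(self, result_root):
        grid, curve = result_root.theta_grid, result_root.dP_curve
        k = int(np.nanargmin(curve))
        assert grid[max(k - 1, 0)] <= result_root.theta_opt \
            <= grid[min(k + 1, len(grid) - 1)]
        assert result_root.dP_min <= np.nanmin(curve) + 1e-9

    def test_apex_biased_allocation_is_optimal(self, result_root):
        assert -0.35 < result_root.theta_opt < 0.0

    def test_uniform_unloading_favors_more_apical_allocation(self, pine_sw2cm,
                                                             result_root):
        uni = optimize_phloem_allocation(pine_sw2cm, "uniform", settings=FAST)
        assert uni.theta_opt < result_root.theta_opt

    def test_optimum_invariant_to_absolute_conductivity_base(self, pine_sw2cm,
                                                             result_root):
        """Scaling the (arbitrary) conduit base rescales conductance only;
        calibration absorbs it and the optimum must not move."""
        scaled = TreeSpec(params=PINE.with_(alpha6=10.0 * PINE.alpha6),
                          L=10.0, r_sw_max=0.02)
        res = optimize_phloem_allocation(scaled, "root", settings=FAST)
        assert res.theta_opt == pytest.approx(result_root.theta_opt, abs=0.02)

    def test_grid_must_span_the_search_interval(self, pine_sw2cm):
        with pytest.raises(ValueError):
            optimize_phloem_allocation(pine_sw2cm, "root",
                                       theta_grid=np.linspace(-0.5, 0.2, 8),
                                       settings=FAST)


@pytest.fixture(scope="module")
def sweep_nohw(pine_nohw):
    return run_height_sweep(pine_nohw, heights=(2, 5, 10, 15, 20, 30),
                            settings=FAST)


class TestHeightSweep:

    def test_assimilation_tracks_transpiration_exactly(self, sweep_nohw):
        ok = sweep_nohw[sweep_nohw.feasible]
        from treevasc.transport import M_WATER, RHO_WATER
        np.testing.assert_allclose(
            ok["A"], ok["E"] * RHO_WATER / M_WATER / FAST.WUE, rtol=1e-12)

    def test_transpiration_per_leaf_area_declines_with_height(self, pine_nohw,
                                                              sweep_nohw):
        from dataclasses import replace
        from treevasc.wholetree import leaf_area
        sub = sweep_nohw.query("unloading == 'root' and kp_multiplier == 1.0")
        e = [row.E / leaf_area(replace(pine_nohw, L=row.L))
             for row in sub.itertuples()]
        assert np.all(np.diff(e) < 0)

    def test_higher_phloem_conductance_lowers_the_turgor_drop(self, sweep_nohw):
        sub = sweep_nohw.query("unloading == 'root'")
        for L, grp in sub.groupby("L"):
            g = grp.set_index("kp_multiplier")["dP"]
            if np.isfinite(g[2.0]) and np.isfinite(g[1.0]):
                assert g[2.0] < g[1.0]

    def test_low_conductance_fails_to_export_sugar_in_tall_trees(self, sweep_nohw):
        sub = sweep_nohw.query("unloading == 'root'")
        tall_low = sub.query("kp_multiplier == 0.5 and L > 15")
        assert not tall_low["converged"].any()
        doubled = sub.query("kp_multiplier == 2.0")
        assert doubled["converged"].all()

    def test_failures_are_flagged_rows_not_dropped(self, sweep_nohw):
        assert len(sweep_nohw) == 6 * 2 * 3

    def test_gravity_free_fixed_viscosity_drop_is_the_series_closed_form(
            self, pine_sw2cm):
        """Without gravity and viscosity feedback the drop is exactly
        loading * eta_rel / (c_leaf * K_p_tot)."""
        from treevasc.transport import water_viscosity
        model = calibrated_model(pine_sw2cm, FAST)
        eta = 1.5e-3
        st = model.solve("root", gravity=False, fixed_viscosity=eta,
                         loading_rate=model.loading_rate * 1e-3, E=0.0)
        K_p = model.grid.total_conductance("p")
        expected = (model.loading_rate * 1e-3 / FAST.c_leaf) \
            * (eta / water_viscosity(FAST.T)) / K_p
        assert st.turgor_difference == pytest.approx(expected, rel=1e-3)
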