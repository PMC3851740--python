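"""Münch solver: viscosity law, conservation laws, oracles, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treevasc import (TreeSpec, PINE, TransportBoundary, TransportError,
                      TransportGrid, axial_profiles, calibrate_phloem_scale,
                      solve_steady_state, viscosity)
from treevasc.transport import (R_GAS, RHO_W_G, sucrose_mass_fraction,
                                water_viscosity, xylem_potential_profile)

RT = R_GAS * 293.0 * 1e-6  # MPa per mol/m^3


def _uniform_grid(L=10.0, n=50, k_x=1e-4, k_p=1e-6, **kw):
    x = np.linspace(0.1, L, n)
    return TransportGrid(x=x, k_x_rel=np.full(n, k_x), k_p_rel=np.full(n, k_p),
                         **kw)


def test_viscosity_of_water_at_zero_concentration():
    assert viscosity(0.0, 293.0) == pytest.approx(water_viscosity(293.0))
    assert water_viscosity(293.0) == pytest.approx(1.00e-3, rel=0.02)


def test_viscosity_at_20_percent_mass_fraction():
    """Relative viscosity at w = 0.2 equals the correlation evaluated
    directly: exp(2.09*0.2 + 6.14*0.04) = 1.9418."""
    # invert w=0.2 -> molarity: c*M = w * rho(w)
    rho = 997.0 + 385.0 * 0.2
    c = 0.2 * rho / 0.3423
    assert sucrose_mass_fraction(c) == pytest.approx(0.2, rel=1e-10)
    assert viscosity(c) / water_viscosity() == pytest.approx(1.9418, abs=2e-4)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(c1=st.floats(0.0, 2000.0), c2=st.floats(0.0, 2000.0))
def test_viscosity_is_strictly_increasing(c1, c2):
    lo, hi = sorted((c1, c2))
    if hi - lo > 1e-9:
        assert viscosity(hi) > viscosity(lo)


def test_viscosity_rejects_negative_concentration():
    with pytest.raises(ValueError):
        viscosity(-1.0)


def test_equilibrium_state_without_fluxes():
    """No loading, no transpiration: uniform sugar, hydrostatic turgor,
    psi_x = psi_soil - rho g z."""
    grid = _uniform_grid()
    b = TransportBoundary(E=0.0, loading_rate=0.0, c_leaf=500.0,
                          psi_soil=-0.2)
    st_ = solve_steady_state(grid, b)
    np.testing.assert_allclose(st_.c, 500.0, rtol=1e-12)
    np.testing.assert_allclose(st_.psi_x, -0.2 - RHO_W_G * st_.z, atol=1e-12)
    np.testing.assert_allclose(np.diff(st_.P_p), RHO_W_G * np.diff(-st_.z),
                               atol=1e-12)


def test_one_segment_closed_form_oracle():
    """Single segment, root unloading, fixed viscosity: the turgor drop is
    loading*eta_rel/(c_leaf*K_seg) minus the gravity gain."""
    x = np.array([0.1, 10.0])
    k_p = 2e-7
    grid = TransportGrid(x=x, k_x_rel=np.full(2, 1e-4), k_p_rel=np.full(2, k_p))
    eta_fix = 2.5e-3
    b = TransportBoundary(E=0.0, loading_rate=1e-6, c_leaf=800.0,
                          fixed_viscosity=eta_fix)
    st_ = solve_steady_state(grid, b)
    dz = x[1] - x[0]
    R_seg = dz / k_p                     # both nodes share the conductivity
    Q = 1e-6 / 800.0
    expected = Q * (eta_fix / water_viscosity(293.0)) * R_seg - RHO_W_G * dz
    assert st_.turgor_difference == pytest.approx(expected, rel=1e-12)


def test_vant_hoff_equilibrium_holds_at_every_node(pine_sw2cm):
    prof = axial_profiles(pine_sw2cm, n_grid=128)
    grid = TransportGrid.from_profile(prof, k_x_scale=3e-4, k_p_scale=1e-4)
    b = TransportBoundary(E=3e-7, loading_rate=5e-6, c_leaf=1200.0)
    st_ = solve_steady_state(grid, b)
    np.testing.assert_allclose(st_.P_p - RT * st_.c, st_.psi_x, atol=1e-9)


def test_water_and_sugar_conservation():
    grid = _uniform_grid(n=80)
    for mode in ("root", "uniform"):
        b = TransportBoundary(E=1e-7, loading_rate=2e-6, c_leaf=900.0,
                              unloading_mode=mode)
        st_ = solve_steady_state(grid, b)
        # sugar: total unloading equals loading
        assert st_.unloading.sum() == pytest.approx(b.loading_rate, rel=1e-12)
        # water: phloem intake at the apex equals the summed lateral return
        assert st_.lateral_water.sum() == pytest.approx(0.0, abs=1e-18)
        assert st_.lateral_water[0] == pytest.approx(-st_.Q_p[0])
        # fluxes follow conservation segment by segment
        np.testing.assert_allclose(
            st_.J_s, b.loading_rate - np.cumsum(st_.unloading)[:-1], atol=1e-18)


def test_xylem_profile_matches_series_resistor_closed_form(pine_nohw):
    prof = axial_profiles(pine_nohw, n_grid=200)
    grid = TransportGrid.from_profile(prof, k_x_scale=5e-4)
    E = 4e-7
    b = TransportBoundary(E=E, loading_rate=0.0, c_leaf=500.0, psi_soil=-0.1)
    psi = xylem_potential_profile(grid, b)
    K_tot = grid.total_conductance("x")
    span = grid.x[-1] - grid.x[0]
    assert psi[0] == pytest.approx(-0.1 - E / K_tot - RHO_W_G * span, rel=1e-12)


def test_grid_refinement_changes_turgor_drop_below_one_percent(pine_sw2cm):
    out = {}
    for n in (200, 400):
        prof = axial_profiles(pine_sw2cm, n_grid=n)
        grid = TransportGrid.from_profile(prof, k_x_scale=3e-4, k_p_scale=2e-4)
        b = TransportBoundary(E=3e-7, loading_rate=5e-6, c_leaf=1200.0)
        out[n] = solve_steady_state(grid, b).turgor_difference
    assert abs(out[400] - out[200]) / abs(out[400]) < 0.01


def test_turgor_drop_decreases_monotonically_in_conductance(pine_sw2cm):
    prof = axial_profiles(pine_sw2cm, n_grid=128)
    b = TransportBoundary(E=3e-7, loading_rate=5e-6, c_leaf=1200.0)
    drops = []
    for s in np.geomspace(1e-4, 1e-3, 6):  # 10x range
        grid = TransportGrid.from_profile(prof, k_x_scale=3e-4, k_p_scale=s)
        drops.append(solve_steady_state(grid, b).turgor_difference)
    assert np.all(np.diff(drops) < 0)


def test_unsustainable_flux_raises_diagnostic_error():
    grid = _uniform_grid(k_p=1e-9)
    b = TransportBoundary(E=1e-7, loading_rate=1e-5, c_leaf=400.0)
    with pytest.raises(TransportError) as err:
        solve_steady_state(grid, b)
    assert err.value.node_index is not None
    assert err.value.max_concentration >= 400.0


class TestCalibration:
    def _solver(self, pine_sw2cm):
        prof = axial_profiles(pine_sw2cm, n_grid=128)
        b = TransportBoundary(E=3e-7, loading_rate=5e-6, c_leaf=1200.0)

        def dP(scale):
            grid = TransportGrid.from_profile(prof, k_x_scale=3e-4,
                                              k_p_scale=scale)
            return solve_steady_state(grid, b).turgor_difference
        return dP

    def test_roundtrip_reaches_target(self, pine_sw2cm):
        dP = self._solver(pine_sw2cm)
        s = calibrate_phloem_scale(dP, target_dP=0.7)
        assert dP(s) == pytest.approx(0.7, abs=1e-3)

    def test_self_target_returns_unit_scale(self, pine_sw2cm):
        dP = self._solver(pine_sw2cm)
        current = dP(1.0)
        assert calibrate_phloem_scale(dP, target_dP=current) \
            == pytest.approx(1.0, abs=1e-6)

    def test_doubling_scale_roughly_halves_the_friction_drop(self, pine_sw2cm):
        prof = axial_profiles(pine_sw2cm, n_grid=128)
        # tiny loading: negligible viscosity feedback along the path
        b = TransportBoundary(E=3e-8, loading_rate=5e-8, c_leaf=1200.0)

        def friction(scale):
            grid = TransportGrid.from_profile(prof, k_x_scale=3e-4,
                                              k_p_scale=scale)
            st_ = solve_steady_state(grid, b)
            span = st_.x[-1] - st_.x[0]
            return st_.turgor_difference + RHO_W_G * span

        assert friction(1e-4) / friction(2e-4) == pytest.approx(2.0, rel=0.05)

    def test_unreachable_target_is_reported(self, pine_sw2cm):
        dP = self._solver(pine_sw2cm)
        with pytest.raises(ValueError, match="not bracketed"):
            calibrate_phloem_scale(dP, target_dP=-5.0)
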