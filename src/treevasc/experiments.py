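"""The three transport simulations built on the scaling profiles.

1. Axial pressure/concentration gradients of a reference tree (10 m pine
   with a 2 cm sapwood cap), for root vs distributed unloading.
2. "Optimal" axial allocation of phloem tissue: redistribute the summed
   phloem cross-section as ``x**theta`` at fixed whole-tree phloem volume
   and find the theta minimizing the leaf-to-root turgor difference.
3. Height sweep under isohydric gas exchange: transpiration set so leaf
   xylem water potential stays fixed, photosynthesis tied to transpiration
   through the water-use efficiency, phloem conductance scaled from the
   structural profiles; the turgor difference is followed across tree
   heights and conductance multipliers.

Absolute conductance anchors: the xylem scale is set so the reference tree
transpires a prescribed flux per unit leaf area at the isohydric leaf water
potential; the phloem scale is calibrated so the reference tree's
leaf-to-root turgor difference equals the target (0.7 MPa) under root
unloading — separately for each heartwood scenario, mirroring how the
simulation design anchors "reasonable" absolute values.  All reported
optima and scaling behaviours are invariant to these anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .params import TreeSpec
from .structure import axial_profiles
from .transport import (M_WATER, R_GAS, RHO_W_G, RHO_WATER, TransportBoundary,
                        TransportError, TransportGrid, TransportState,
                        calibrate_phloem_scale, solve_steady_state)
from .wholetree import leaf_area


@dataclass(frozen=True)
class SimulationSettings:
    """Physiological constants and anchors shared by the simulations.

    ``psi_leaf``: isohydric leaf xylem water potential, MPa.
    ``WUE``: water-use efficiency, mol H2O transpired per mol CO2 fixed.
    ``sucrose_carbon``: CO2 per sucrose (12).
    ``e_leaf_ref``: reference transpiration per leaf area (m^3 m^-2 s^-1)
    used to anchor the absolute xylem conductance at ``reference_L``.
    ``dP_target``: calibrated leaf-to-root turgor difference, MPa.
    ``sink_turgor``: root/sink turgor anchor (MPa) fixing the source sieve
    concentration: ``c_leaf = (sink_turgor + dP_target - psi_leaf) / RT``.
    """

    psi_leaf: float = -2.0
    psi_soil: float = 0.0
    T: float = 293.0
    WUE: float = 250.0
    sucrose_carbon: float = 12.0
    e_leaf_ref: float = 1.16e-8
    reference_L: float = 10.0
    dP_target: float = 0.7
    sink_turgor: float = 0.1
    n_nodes: int = 400

    @property
    def c_leaf(self) -> float:
        RT = R_GAS * self.T * 1e-6
        return (self.sink_turgor + self.dP_target - self.psi_soil
                - self.psi_leaf) / RT


DEFAULT_SETTINGS = SimulationSettings()


@dataclass
class CalibratedModel:
    """Transport model of one tree with calibrated conductance scales."""

    tree: TreeSpec
    settings: SimulationSettings
    grid: TransportGrid
    E: float                 # m^3/s
    loading_rate: float      # mol sucrose / s
    phloem_volume: float     # m^3 on the solver grid

    def boundary(self, unloading_mode: str = "root",
                 **overrides) -> TransportBoundary:
        kw = dict(E=self.E, loading_rate=self.loading_rate,
                  c_leaf=self.settings.c_leaf,
                  unloading_mode=unloading_mode,
                  psi_soil=self.settings.psi_soil, T=self.settings.T)
        kw.update(overrides)
        return TransportBoundary(**kw)

    def solve(self, unloading_mode: str = "root", **overrides) -> TransportState:
        return solve_steady_state(self.grid, self.boundary(unloading_mode,
                                                           **overrides))


def _available_drawdown(tree: TreeSpec, settings: SimulationSettings) -> float:
    """Soil-to-leaf pressure difference left for friction, MPa."""
    return (settings.psi_soil - settings.psi_leaf
            - RHO_W_G * (tree.L - tree.L0))


def xylem_scale(tree_template: TreeSpec,
                settings: SimulationSettings = DEFAULT_SETTINGS) -> float:
    """Absolute xylem conductance per relative unit for this scenario.

    Chosen so the reference-height tree transpires ``e_leaf_ref`` per unit
    leaf area when the whole available soil-to-leaf drawdown drives it.
    """
    ref = replace(tree_template, L=settings.reference_L)
    prof = axial_profiles(ref, n_grid=settings.n_nodes)
    grid = TransportGrid.from_profile(prof)
    E_ref = settings.e_leaf_ref * leaf_area(ref)
    avail = _available_drawdown(ref, settings)
    if avail <= 0:
        raise ValueError("reference tree infeasible: gravity exceeds drawdown")
    return E_ref / (grid.total_conductance("x") * avail)


def _loading_from_E(E: float, settings: SimulationSettings) -> float:
    mol_water = E * RHO_WATER / M_WATER
    return mol_water / settings.WUE / settings.sucrose_carbon


def build_model(tree: TreeSpec,
                settings: SimulationSettings = DEFAULT_SETTINGS,
                k_x_scale: float | None = None,
                k_p_scale: float = 1.0) -> CalibratedModel:
    """Assemble grid and isohydric boundary fluxes for one tree (uncalibrated
    phloem scale unless given)."""
    if k_x_scale is None:
        k_x_scale = xylem_scale(tree, settings)
    prof = axial_profiles(tree, n_grid=settings.n_nodes)
    grid = TransportGrid.from_profile(prof, k_x_scale=k_x_scale,
                                      k_p_scale=k_p_scale)
    avail = _available_drawdown(tree, settings)
    if avail <= 0:
        raise ValueError("infeasible height: gravity exceeds the drawdown")
    E = grid.total_conductance("x") * avail
    return CalibratedModel(
        tree=tree, settings=settings, grid=grid, E=E,
        loading_rate=_loading_from_E(E, settings),
        phloem_volume=float(np.trapezoid(prof.A_p_tot, prof.x)),
    )


def calibrate_scenario(tree_template: TreeSpec,
                       settings: SimulationSettings = DEFAULT_SETTINGS) -> float:
    """Calibrated phloem-conductance scale for one heartwood scenario.

    The reference-height tree with root unloading must reach the target
    leaf-to-root turgor difference.
    """
    ref = replace(tree_template, L=settings.reference_L)
    k_x = xylem_scale(tree_template, settings)
    base = build_model(ref, settings, k_x_scale=k_x)

    def dP(scale: float) -> float:
        grid = TransportGrid(x=base.grid.x, k_x_rel=base.grid.k_x_rel,
                             k_p_rel=base.grid.k_p_rel,
                             k_x_scale=k_x, k_p_scale=scale)
        st = solve_steady_state(grid, base.boundary("root"))
        return st.turgor_difference

    return calibrate_phloem_scale(dP, target_dP=settings.dP_target)


def calibrated_model(tree: TreeSpec,
                     settings: SimulationSettings = DEFAULT_SETTINGS) -> CalibratedModel:
    """Model with both conductance anchors resolved for this scenario."""
    return build_model(tree, settings,
                       k_x_scale=xylem_scale(tree, settings),
                       k_p_scale=calibrate_scenario(tree, settings))


# ---------------------------------------------------------------------------
# simulation 1: axial gradients


@dataclass
class AxialExperimentResult:
    state: TransportState
    unloading_mode: str
    #: fraction of the total phloem turgor drop in the basal half of the path
    basal_half_turgor_fraction: float
    #: xylem potential drop per metre in the apical / basal 10% of the path
    apical_psi_gradient: float
    basal_psi_gradient: float

    def normalized_profiles(self) -> pd.DataFrame:
        """Profiles scaled to their values at the tree base."""
        s = self.state
        return pd.DataFrame({
            "x_m": s.x,
            "psi_x_rel": s.psi_x / s.psi_x[-1] if s.psi_x[-1] != 0 else s.psi_x,
            "P_p_rel": s.P_p / s.P_p[-1],
            "c_rel": s.c / s.c[-1],
        })


def _drop_fraction_basal_half(state: TransportState) -> float:
    x = state.x
    mid = 0.5 * (x[0] + x[-1])
    P = state.P_p
    total = P[0] - P[-1]
    P_mid = float(np.interp(mid, x, P))
    return (P_mid - P[-1]) / total


def _gradient_in_band(x, psi, lo_frac, hi_frac) -> float:
    span = x[-1] - x[0]
    a = x[0] + lo_frac * span
    b = x[0] + hi_frac * span
    return abs(float(np.interp(b, x, psi) - np.interp(a, x, psi))) / (b - a)


def run_axial_profile_experiment(tree: TreeSpec, unloading_mode: str = "root",
                                 settings: SimulationSettings = DEFAULT_SETTINGS
                                 ) -> AxialExperimentResult:
    model = calibrated_model(tree, settings)
    state = model.solve(unloading_mode)
    return AxialExperimentResult(
        state=state, unloading_mode=unloading_mode,
        basal_half_turgor_fraction=_drop_fraction_basal_half(state),
        apical_psi_gradient=_gradient_in_band(state.x, state.psi_x, 0.0, 0.1),
        basal_psi_gradient=_gradient_in_band(state.x, state.psi_x, 0.9, 1.0),
    )


# ---------------------------------------------------------------------------
# simulation 2: optimal phloem allocation


@dataclass
class AllocationSearchResult:
    theta_opt: float
    theta_grid: np.ndarray
    dP_curve: np.ndarray          # MPa; NaN where the solve failed
    unloading_mode: str
    volume_residual: float        # max relative phloem-volume error over grid
    dP_min: float


def reallocated_grid(model: CalibratedModel, theta: float) -> TransportGrid:
    """Grid with A_p,tot ∝ x**theta at the reference phloem volume.

    The conduit-taper and lumen-fraction factors (k_p per unit area) are
    kept from the structural profile; only the area profile is reshaped.
    """
    x = model.grid.x
    prof = axial_profiles(model.tree, n_grid=model.settings.n_nodes)
    per_area = prof.k_p / prof.A_p_tot
    shape = x ** theta
    shape *= model.phloem_volume / np.trapezoid(shape, x)
    return TransportGrid(
        x=x, k_x_rel=model.grid.k_x_rel, k_p_rel=shape * per_area,
        k_x_scale=model.grid.k_x_scale, k_p_scale=model.grid.k_p_scale,
    )


def optimize_phloem_allocation(tree: TreeSpec, unloading_mode: str = "root",
                               theta_grid=None,
                               settings: SimulationSettings = DEFAULT_SETTINGS,
                               refine_tol: float = 5e-3
                               ) -> AllocationSearchResult:
    """Find the allocation exponent minimizing the turgor difference.

    Coarse scan over ``theta_grid`` (default 13 points on [-1, 0.5]), then
    bounded golden-section refinement around the grid minimum to
    ``refine_tol`` in theta.  Whole-tree phloem volume is conserved at
    every theta by construction (trapezoid on the solver grid).
    """
    if theta_grid is None:
        theta_grid = np.linspace(-1.0, 0.5, 13)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.min() > -1.0 + 1e-9 or theta_grid.max() < 0.5 - 1e-9:
        raise ValueError("theta_grid must span at least [-1, 0.5]")
    model = calibrated_model(tree, settings)
    prof = axial_profiles(tree, n_grid=settings.n_nodes)
    per_area = prof.k_p / prof.A_p_tot
    x = model.grid.x

    vol_resid = 0.0

    def dP(theta: float) -> float:
        nonlocal vol_resid
        shape = x ** theta
        shape *= model.phloem_volume / np.trapezoid(shape, x)
        resid = abs(np.trapezoid(shape, x) - model.phloem_volume) \
            / model.phloem_volume
        vol_resid = max(vol_resid, resid)
        grid = TransportGrid(
            x=x, k_x_rel=model.grid.k_x_rel, k_p_rel=shape * per_area,
            k_x_scale=model.grid.k_x_scale, k_p_scale=model.grid.k_p_scale)
        st = solve_steady_state(grid, model.boundary(unloading_mode))
        return st.turgor_difference

    curve = np.full(theta_grid.size, np.nan)
    for i, th in enumerate(theta_grid):
        try:
            curve[i] = dP(float(th))
        except TransportError:
            pass
    if np.all(np.isnan(curve)):
        raise TransportError("no allocation exponent admitted a steady state")
    k = int(np.nanargmin(curve))
    lo = theta_grid[max(k - 1, 0)]
    hi = theta_grid[min(k + 1, theta_grid.size - 1)]

    def safe_dP(th: float) -> float:
        try:
            return dP(th)
        except TransportError:
            return np.inf

    res = minimize_scalar(safe_dP, bounds=(lo, hi), method="bounded",
                          options={"xatol": refine_tol})
    return AllocationSearchResult(
        theta_opt=float(res.x), theta_grid=theta_grid, dP_curve=curve,
        unloading_mode=unloading_mode, volume_residual=vol_resid,
        dP_min=float(res.fun),
    )


# ---------------------------------------------------------------------------
# simulation 3: height sweep


DEFAULT_HEIGHTS = (2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)


def run_height_sweep(tree_template: TreeSpec,
                     heights=DEFAULT_HEIGHTS,
                     unloading_modes=("root", "uniform"),
                     kp_multipliers=(0.5, 1.0, 2.0),
                     settings: SimulationSettings = DEFAULT_SETTINGS
                     ) -> pd.DataFrame:
    """Turgor difference vs tree height under isohydric gas exchange.

    Per height: E = K_x,tot * (psi_soil - psi_leaf - rho g L); assimilation
    A = E/WUE (molar); loading = A / sucrose stoichiometry; the calibrated
    scenario phloem scale is multiplied by each entry of
    ``kp_multipliers``.  Infeasible heights (gravity exhausts the drawdown)
    and non-converged solves are flagged, never dropped.
    """
    k_x = xylem_scale(tree_template, settings)
    k_p_cal = calibrate_scenario(tree_template, settings)
    scenario = ("sw-cap" if tree_template.has_heartwood_cap else "no-hw")
    rows = []
    for L in heights:
        tree = replace(tree_template, L=float(L))
        try:
            model = build_model(tree, settings, k_x_scale=k_x)
        except ValueError:
            for mode in unloading_modes:
                for mult in kp_multipliers:
                    rows.append(dict(
                        scenario=scenario, L=L, unloading=mode,
                        kp_multiplier=mult, E=np.nan, A=np.nan, dP=np.nan,
                        feasible=False, converged=False))
            continue
        A = model.E * RHO_WATER / M_WATER / settings.WUE  # mol CO2 / s
        for mode in unloading_modes:
            for mult in kp_multipliers:
                grid = TransportGrid(
                    x=model.grid.x, k_x_rel=model.grid.k_x_rel,
                    k_p_rel=model.grid.k_p_rel, k_x_scale=k_x,
                    k_p_scale=k_p_cal * mult)
                try:
                    st = solve_steady_state(grid, model.boundary(mode))
                    dP, conv = st.turgor_difference, True
                except TransportError:
                    dP, conv = np.nan, False
                rows.append(dict(
                    scenario=scenario, L=L, unloading=mode,
                    kp_multiplier=mult, E=model.E, A=A, dP=dP,
                    feasible=True, converged=conv))
    return pd.DataFrame(rows)
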