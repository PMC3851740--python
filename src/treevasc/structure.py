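"""Axial tree structure: taper, tissue power laws, pipe-model bookkeeping.

Per-height totals follow from three ingredients: the taper law mapping
distance-from-apex to diameter, the tissue power laws in diameter, and the
pipe-model assumption that the summed sapwood cross-sectional area is
conserved across branching junctions.  The furcation number (parallel axis
count) at distance ``x`` from the apex is then the ratio of basal sapwood
area to the per-axis sapwood area at ``x``; with no heartwood this reduces
to ``(L/x)**(delta*beta1)``.

Heartwood is modelled as an annulus rule: conducting sapwood occupies at
most the outermost ``r_sw_max`` metres of the xylem radius (radius taken as
the equivalent radius of the xylem area, not the over-bark radius, to avoid
counting bark).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ScalingParams, TreeSpec

MM2_TO_M2 = 1e-6


def diameter_at_distance(x, params: ScalingParams):
    """Diameter (mm) at distance ``x`` (m) from the apex: gamma * x**delta."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("distance from apex must be positive")
    return params.gamma * x ** params.delta


def tissue_property(d, base: float, exponent: float):
    """Evaluate a tissue power law ``base * d**exponent`` at diameter d (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    return base * d ** exponent


def xylem_area_mm2(d, params: ScalingParams):
    return tissue_property(d, params.alpha1, params.beta1)


def phloem_area_mm2(d, params: ScalingParams):
    return tissue_property(d, params.alpha2, params.beta2)


def sapwood_partition(d, tree: TreeSpec):
    """Split the xylem area at diameter ``d`` (mm) into sapwood and heartwood.

    Returns ``(A_sw, A_hw)`` in mm^2.  The equivalent xylem radius is
    ``sqrt(A_x/pi)``; if it does not exceed the sapwood-depth cap the whole
    section conducts, otherwise sapwood is the outer annulus of radial depth
    ``r_sw_max`` and heartwood the remaining core.
    """
    A_x = xylem_area_mm2(d, tree.params)
    if not tree.has_heartwood_cap:
        return A_x, np.zeros_like(A_x)
    r_max_mm = tree.r_sw_max * 1000.0
    r = np.sqrt(A_x / np.pi)
    annulus = np.pi * (r ** 2 - (r - r_max_mm) ** 2)
    A_sw = np.where(r <= r_max_mm, A_x, annulus)
    return A_sw, A_x - A_sw


def sapwood_area_mm2(d, tree: TreeSpec):
    return sapwood_partition(d, tree)[0]


def heartwood_transition_distance(tree: TreeSpec):
    """Distance from apex (m) where heartwood first appears, or None.

    Solves ``A_x(d(x)) = pi * r_sw_max**2`` on the closed form.
    """
    if not tree.has_heartwood_cap:
        return None
    p = tree.params
    r_max_mm = tree.r_sw_max * 1000.0
    # alpha1 * d**beta1 = pi r^2  ->  d* ; then x* from the taper law
    d_star = (np.pi * r_max_mm ** 2 / p.alpha1) ** (1.0 / p.beta1)
    x_star = (d_star / p.gamma) ** (1.0 / p.delta)
    if x_star >= tree.L:
        return None  # tree too small: all sapwood
    return float(x_star)


def furcation_number(x, tree: TreeSpec):
    """Number of parallel axes at distance ``x`` from the apex (>= 1).

    Pipe-model sapwood conservation: ``n(x) = A_sw(d(L)) / A_sw(d(x))``.
    A heartwood cap lowers the basal sapwood area and hence lowers ``n``
    everywhere above the transition (fewer unit pipes are supported).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < tree.L0 - 1e-12) or np.any(x > tree.L + 1e-12):
        raise ValueError("x must lie within [L0, L]")
    base = sapwood_area_mm2(diameter_at_distance(tree.L, tree.params), tree)
    local = sapwood_area_mm2(diameter_at_distance(x, tree.params), tree)
    return base / local


@dataclass
class AxialProfile:
    """Per-height whole-crown totals on a grid of distances from the apex.

    Areas are in m^2, nitrogen line densities in g m^-1, conductivities in
    relative units (arbitrary absolute scale).  ``A_x_tot`` includes the
    heartwood cross-section; ``A_sw_tot`` is the conducting part only (the
    two coincide without a heartwood cap).
    """

    tree: TreeSpec
    x: np.ndarray            # m from apex, ascending
    d: np.ndarray            # mm
    A_x: np.ndarray          # per-axis xylem area, m^2
    A_p: np.ndarray          # per-axis phloem area, m^2
    A_sw: np.ndarray         # per-axis sapwood area, m^2
    A_hw: np.ndarray         # per-axis heartwood area, m^2
    n: np.ndarray            # furcation number, >= 1
    A_sw_tot: np.ndarray     # n * A_sw, m^2
    A_x_tot: np.ndarray      # n * (A_sw + A_hw), m^2
    A_p_tot: np.ndarray      # n * A_p, m^2
    N_line_x: np.ndarray     # g N per m of height, xylem
    N_line_p: np.ndarray     # g N per m of height, phloem
    k_x: np.ndarray          # relative axial conductivity, xylem
    k_p: np.ndarray          # relative axial conductivity, phloem

    @property
    def z(self) -> np.ndarray:
        """Height above the base, m (base of the path at x = L)."""
        return self.tree.L - self.x


def axial_profiles(tree: TreeSpec, n_grid: int = 256,
                   spacing: str = "log") -> AxialProfile:
    """Evaluate all per-height totals on a grid over [L0, L].

    ``spacing`` is "log" (default; power laws are equidistributed in
    relative error) or "linear" (uniform in path length, which is how the
    measured axial profiles sample the stem).
    """
    if n_grid < 16:
        raise ValueError("n_grid must be >= 16")
    if spacing == "log":
        x = np.logspace(np.log10(tree.L0), np.log10(tree.L), n_grid)
    elif spacing == "linear":
        x = np.linspace(tree.L0, tree.L, n_grid)
    else:
        raise ValueError("spacing must be 'log' or 'linear'")
    p = tree.params
    d = diameter_at_distance(x, p)
    A_x = xylem_area_mm2(d, p) * MM2_TO_M2
    A_p = phloem_area_mm2(d, p) * MM2_TO_M2
    A_sw_mm, A_hw_mm = sapwood_partition(d, tree)
    A_sw = A_sw_mm * MM2_TO_M2
    A_hw = A_hw_mm * MM2_TO_M2
    n = furcation_number(x, tree)

    rho_N_x = tissue_property(d, p.alpha3, p.beta3) / 100.0   # mass fraction
    rho_N_p = tissue_property(d, p.alpha4, p.beta4) / 100.0
    r_x = tissue_property(d, p.alpha5, p.beta5)
    r_p = tissue_property(d, p.alpha6, p.beta6)
    rho_c_x = tissue_property(d, p.alpha7, p.beta7)
    rho_c_p = tissue_property(d, p.alpha8, p.beta8)

    # nitrogen-bearing xylem area: sapwood plus a scenario fraction of the
    # heartwood concentration
    A_x_nitrogen = A_sw + tree.hw_nitrogen_fraction * A_hw
    N_line_x = n * A_x_nitrogen * p.wood_density * rho_N_x * 1000.0  # g/m
    N_line_p = n * A_p * p.phloem_density * rho_N_p * 1000.0

    return AxialProfile(
        tree=tree, x=x, d=d, A_x=A_x, A_p=A_p, A_sw=A_sw, A_hw=A_hw, n=n,
        A_sw_tot=n * A_sw, A_x_tot=n * (A_sw + A_hw), A_p_tot=n * A_p,
        N_line_x=N_line_x, N_line_p=N_line_p,
        k_x=n * A_sw * rho_c_x * r_x ** 2,
        k_p=n * A_p * rho_c_p * r_p ** 2,
    )


def fit_loglog_exponent(x, y) -> tuple[float, float]:
    """OLS slope and intercept of ln(y) on ln(x).  Returns (exponent, base)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit needs positive data")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return float(slope), float(np.exp(intercept))


def axial_scaling_exponent(tree: TreeSpec, field: str, n_grid: int = 200,
                           spacing: str = "linear") -> float:
    """Fitted log-log exponent of a profile field against distance from apex.

    The default linear grid weights the fit uniformly in path length, which
    matches how axial profiles are sampled along a harvested stem; pure
    power-law fields give the same exponent for any spacing.
    """
    prof = axial_profiles(tree, n_grid=n_grid, spacing=spacing)
    return fit_loglog_exponent(prof.x, getattr(prof, field))[0]


def profile_frame(prof: AxialProfile):
    """Profile as a tidy pandas DataFrame (for CSV export)."""
    import pandas as pd

    return pd.DataFrame({
        "x_m": prof.x, "d_mm": prof.d, "n": prof.n,
        "A_x_m2": prof.A_x, "A_p_m2": prof.A_p,
        "A_sw_m2": prof.A_sw, "A_hw_m2": prof.A_hw,
        "A_sw_tot_m2": prof.A_sw_tot, "A_x_tot_m2": prof.A_x_tot,
        "A_p_tot_m2": prof.A_p_tot,
        "N_line_x_g_per_m": prof.N_line_x, "N_line_p_g_per_m": prof.N_line_p,
        "k_x_rel": prof.k_x, "k_p_rel": prof.k_p,
    })
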