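"""Steady-state coupled xylem-phloem (Münch) transport.

The tree is a single transport axis discretized from the apex (where all
leaves sit, in the pipe-model coordinate every branch tip is at the apex
distance) down to the base/root.  The xylem carries the transpiration
stream upward against friction and gravity; the phloem carries the sugar
stream downward, driven by the turgor gradient that osmosis builds on top
of the xylem water-potential profile.  At every node local water-potential
equilibrium is assumed between the two conduits (radial exchange fast
compared with axial transport):

    P_p - R T c = psi_x            (van 't Hoff, ideal osmotic coefficient)

At steady state the sugar flux through every segment is fixed by
conservation (loading at the apex minus the cumulative unloading above the
segment), which turns the coupled system into a single apex-to-base
recursion for concentration and turgor, with an inner fixed point per
segment for the concentration-dependent sap viscosity.  The scheme is
direct and deterministic; non-convergence can only mean the phloem cannot
physically sustain the imposed sugar flux (the concentration would have to
fall below zero), which is reported as a diagnostic error.

Conductance units: segment conductances are stored in relative units with
a multiplicative scale factor (m^3 s^-1 MPa^-1 per relative unit).  The
phloem scale is calibrated so a reference tree reaches a prescribed
leaf-to-root turgor difference (the ~0.7 MPa anchor); the xylem
scale only sets the absolute transpiration and cancels from every
dimensionless result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AxialProfile

R_GAS = 8.314           # J mol^-1 K^-1
RHO_W_G = 9.81e-3       # MPa per m of water column (rho_w * g * 1e-6)
M_SUCROSE = 0.3423      # kg/mol
M_WATER = 0.018         # kg/mol
RHO_WATER = 1000.0      # kg/m^3


class TransportError(RuntimeError):
    """Steady state unattainable; carries diagnostics."""

    def __init__(self, message: str, node_index: int | None = None,
                 max_concentration: float | None = None,
                 last_residual: float | None = None):
        super().__init__(message)
        self.node_index = node_index
        self.max_concentration = max_concentration
        self.last_residual = last_residual


def water_viscosity(T: float = 293.0) -> float:
    """Dynamic viscosity of pure water (Pa s), Vogel-type correlation."""
    return 2.414e-5 * 10.0 ** (247.8 / (T - 140.0))


#: coefficients of the relative-viscosity law exp(a*w + b*w^2) in sucrose
#: mass fraction w, fitted to tabulated 20 C sucrose-solution data
#: (within a few % up to w ~ 0.45)
VISC_A = 2.09
VISC_B = 6.14
#: density of sucrose solution ~ rho_w + slope * w (kg/m^3)
SUCROSE_DENSITY_SLOPE = 385.0


def sucrose_mass_fraction(c) -> np.ndarray:
    """Mass fraction of sucrose for molarity c (mol/m^3 solution)."""
    m = np.asarray(c, dtype=float) * M_SUCROSE  # kg sucrose per m^3
    w = m / 1100.0
    for _ in range(30):
        w = m / (997.0 + SUCROSE_DENSITY_SLOPE * w)
    return w


def viscosity(c, T: float = 293.0):
    """Phloem sap viscosity (Pa s) at sucrose concentration c (mol/m^3).

    Strictly increasing and convex in c; equals the viscosity of water at
    c = 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    w = sucrose_mass_fraction(c)
    rel = np.exp(VISC_A * w + VISC_B * w ** 2)
    out = water_viscosity(T) * rel
    return float(out) if out.ndim == 0 else out


@dataclass
class TransportGrid:
    """Discretized transport axis, apex (index 0) to base (index -1).

    ``x`` are distances from the apex (m, ascending); ``k_x_rel`` and
    ``k_p_rel`` are nodal relative conductivities (flow per unit pressure
    gradient per unit length, at reference viscosity).  ``k_x_scale`` and
    ``k_p_scale`` convert to m^3 s^-1 MPa^-1 m.
    """

    x: np.ndarray
    k_x_rel: np.ndarray
    k_p_rel: np.ndarray
    k_x_scale: float = 1.0
    k_p_scale: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing (apex to base)")
        for k in (self.k_x_rel, self.k_p_rel):
            if np.any(np.asarray(k) <= 0):
                raise ValueError("conductivities must be positive")

    @classmethod
    def from_profile(cls, prof: AxialProfile, k_x_scale: float = 1.0,
                     k_p_scale: float = 1.0) -> "TransportGrid":
        return cls(x=prof.x.copy(), k_x_rel=prof.k_x.copy(),
                   k_p_rel=prof.k_p.copy(),
                   k_x_scale=k_x_scale, k_p_scale=k_p_scale)

    @property
    def n_nodes(self) -> int:
        return self.x.size

    @property
    def dz(self) -> np.ndarray:
        """Segment lengths (m), positive, apex side first."""
        return np.diff(self.x)

    def segment_resistance(self, which: str) -> np.ndarray:
        """Per-segment resistances (MPa s m^-3) at reference viscosity."""
        k = self.k_x_rel if which == "x" else self.k_p_rel
        scale = self.k_x_scale if which == "x" else self.k_p_scale
        kk = k * scale
        return self.dz * 0.5 * (1.0 / kk[:-1] + 1.0 / kk[1:])

    def total_conductance(self, which: str) -> float:
        return 1.0 / float(self.segment_resistance(which).sum())


@dataclass(frozen=True)
class TransportBoundary:
    """Boundary conditions of one steady-state solve.

    ``E``: transpiration (m^3 water / s), extracted at the apex node.
    ``loading_rate``: sugar flux loaded into the phloem at the apex
    (mol sucrose / s), equal to photosynthesis divided by the sucrose
    stoichiometry. ``c_leaf``: sieve-sap sugar concentration at the source
    (mol/m^3), the closure of the steady state.  ``unloading_mode``:
    "root" (all unloading at the basal node) or "uniform" (equal flux per
    unit path length).
    """

    E: float
    loading_rate: float
    c_leaf: float
    unloading_mode: str = "root"
    psi_soil: float = 0.0
    T: float = 293.0
    gravity: bool = True
    fixed_viscosity: float | None = None  # Pa s; bypasses the sap-viscosity law

    def __post_init__(self) -> None:
        if self.E < 0 or self.loading_rate < 0:
            raise ValueError("E and loading_rate must be >= 0")
        if self.c_leaf <= 0:
            raise ValueError("c_leaf must be positive")
        if self.unloading_mode not in ("root", "uniform"):
            raise ValueError("unloading_mode must be 'root' or 'uniform'")


@dataclass
class TransportState:
    """Converged steady state."""

    x: np.ndarray             # m from apex
    z: np.ndarray             # height above base, m
    psi_x: np.ndarray         # MPa
    P_p: np.ndarray           # MPa (turgor)
    c: np.ndarray             # mol/m^3
    Q_p: np.ndarray           # phloem volumetric flow per segment, m^3/s
    J_s: np.ndarray           # sugar flux per segment, mol/s
    unloading: np.ndarray     # per-node unloading, mol/s
    lateral_water: np.ndarray  # per-node water returned to the xylem, m^3/s
    residual: float

    @property
    def turgor_difference(self) -> float:
        """Leaf-to-root turgor difference, MPa."""
        return float(self.P_p[0] - self.P_p[-1])

    @property
    def osmotic_pressure(self) -> np.ndarray:
        return self.P_p - self.psi_x


def _unloading_profile(grid: TransportGrid, boundary: TransportBoundary):
    """Per-node unloading (mol/s) summing to the loading rate."""
    n = grid.n_nodes
    u = np.zeros(n)
    if boundary.unloading_mode == "root":
        u[-1] = boundary.loading_rate
    else:
        dz = grid.dz
        length = np.zeros(n)
        length[:-1] += 0.5 * dz
        length[1:] += 0.5 * dz
        length[0] = 0.0  # the source node does not unload into itself
        u = boundary.loading_rate * length / length.sum()
    return u


def xylem_potential_profile(grid: TransportGrid,
                            boundary: TransportBoundary) -> np.ndarray:
    """psi_x at every node: soil value minus gravity head minus friction.

    The whole transpiration stream traverses every segment (extraction at
    the apex, supply at the soil node); the small phloem counter-current is
    neglected in the xylem balance.
    """
    R = grid.segment_resistance("x")
    z = grid.x[-1] - grid.x
    g = RHO_W_G if boundary.gravity else 0.0
    psi = np.empty(grid.n_nodes)
    psi[-1] = boundary.psi_soil
    for i in range(grid.n_nodes - 2, -1, -1):
        psi[i] = psi[i + 1] - g * (z[i] - z[i + 1]) - boundary.E * R[i]
    return psi


def solve_steady_state(grid: TransportGrid, boundary: TransportBoundary,
                       tol: float = 1e-10,
                       max_inner: int = 200) -> TransportState:
    """Solve the coupled steady state by the apex-to-base recursion.

    Per segment, the phloem volumetric flow is the (conserved) sugar flux
    divided by the upwind concentration; the turgor at the lower node
    follows from friction (with concentration-dependent viscosity at the
    segment mean) minus the hydrostatic gain, and the lower concentration
    from water-potential equilibrium.  The inner loop iterates the segment
    mean concentration to ``tol`` (relative).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = grid.n_nodes
    psi = xylem_potential_profile(grid, boundary)
    u = _unloading_profile(grid, boundary)
    # sugar flux through segment i (between node i and i+1)
    J = boundary.loading_rate - np.cumsum(u)[:-1]
    J = np.clip(J, 0.0, None)

    RT = R_GAS * boundary.T * 1e-6  # MPa per (mol/m^3)
    eta_ref = water_viscosity(boundary.T)
    g = RHO_W_G if boundary.gravity else 0.0
    if boundary.fixed_viscosity is None:
        eta_of = lambda cc: viscosity(cc, boundary.T)
    else:
        eta_of = lambda cc: boundary.fixed_viscosity
    Rseg = grid.segment_resistance("p")
    dz = grid.dz

    c = np.empty(n)
    P = np.empty(n)
    c[0] = boundary.c_leaf
    P[0] = psi[0] + RT * c[0]
    Q = np.zeros(n - 1)
    residual = 0.0
    for i in range(n - 1):
        ci = c[i]
        if J[i] <= 0.0:
            # no sugar flux: no friction, turgor follows hydrostatics
            P[i + 1] = P[i] + g * dz[i]
            cb = (P[i + 1] - psi[i + 1]) / RT
            if cb <= 0:
                raise TransportError(
                    "concentration driven below zero in a flux-free segment",
                    node_index=i + 1, max_concentration=float(np.max(c[:i + 1])))
            c[i + 1] = cb
            continue
        cb = ci
        ok = False
        for _ in range(max_inner):
            eta_rel = eta_of(0.5 * (ci + cb)) / eta_ref
            Qi = J[i] / ci
            Pn = P[i] + g * dz[i] - Qi * eta_rel * Rseg[i]
            cb_new = (Pn - psi[i + 1]) / RT
            if cb_new <= 0:
                raise TransportError(
                    "phloem cannot sustain the sugar flux (sap would be "
                    "exhausted before the sink): viscosity/flow feedback",
                    node_index=i + 1,
                    max_concentration=float(np.max(c[:i + 1])),
                    last_residual=abs(cb_new - cb))
            resid = abs(cb_new - cb) / max(cb, 1e-12)
            cb = cb_new
            if resid < tol:
                ok = True
                break
        if not ok:
            raise TransportError(
                "inner viscosity fixed point did not converge",
                node_index=i + 1, max_concentration=float(np.max(c[:i + 1])),
                last_residual=resid)
        residual = max(residual, resid)
        eta_rel = eta_of(0.5 * (ci + cb)) / eta_ref
        Q[i] = J[i] / ci
        P[i + 1] = P[i] + g * dz[i] - Q[i] * eta_rel * Rseg[i]
        c[i + 1] = (P[i + 1] - psi[i + 1]) / RT

    # lateral water balance: flow divergence leaves the phloem back to the
    # xylem at unloading sites (and enters at the apex)
    lateral = np.zeros(n)
    lateral[0] = -Q[0] if n > 1 else 0.0
    for i in range(1, n - 1):
        lateral[i] = Q[i - 1] - Q[i]
    lateral[-1] = Q[-1] if n > 1 else 0.0

    return TransportState(
        x=grid.x.copy(), z=grid.x[-1] - grid.x, psi_x=psi, P_p=P, c=c,
        Q_p=Q, J_s=J, unloading=u, lateral_water=lateral, residual=residual,
    )


def calibrate_phloem_scale(solve_fn, target_dP: float = 0.7,
                           tol: float = 1e-3,
                           bracket: tuple[float, float] = (1e-12, 1e12)) -> float:
    """Multiplicative phloem-conductance scale reaching a target turgor drop.

    ``solve_fn(scale)`` must return the leaf-to-root turgor difference for
    a given scale (or raise :class:`TransportError`, treated as "drop too
    large").  The turgor drop decreases monotonically in the scale, so the
    root is found by bisection in log-scale to ``tol`` (MPa).
    """
    lo, hi = (np.log(b) for b in bracket)

    def excess(log_s: float) -> float:
        try:
            return solve_fn(float(np.exp(log_s))) - target_dP
        except TransportError:
            return np.inf  # conductance too small: unattainable drop

    f_lo, f_hi = excess(lo), excess(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(
            f"target_dP={target_dP} not bracketed: dP range "
            f"[{f_hi + target_dP:.3g}, {f_lo + target_dP:.3g}]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = excess(mid)
        if abs(f_mid) < tol:
            return float(np.exp(mid))
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration bisection did not converge")
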