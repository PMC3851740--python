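"""Whole-tree totals by integration over the axial profiles.

Without heartwood every total has a closed form: the integrand
``n(x) * P(d(x))`` is itself a power of ``x``, so volumes, nitrogen amounts
and path resistances are incomplete power integrals over [L0, L].  With a
sapwood-depth cap the annulus rule breaks the pure power structure and the
totals are evaluated by composite quadrature of the axial profile, with
grid-doubling refinement.  Height-scaling exponents are then log-log OLS
fits of each total against tree height; the fitted exponent of a
near-allometric quantity depends (mildly) on the fitted height range, which
is therefore carried on every fit result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import ScalingParams, TreeSpec
from .structure import (MM2_TO_M2, axial_profiles, diameter_at_distance,
                        fit_loglog_exponent, sapwood_partition,
                        xylem_area_mm2)


class ScenarioError(ValueError):
    """Closed forms only exist for the no-heartwood scenario."""


@dataclass(frozen=True)
class WholeTreeSummary:
    """Whole-tree totals for one tree instance.

    Volumes in m^3, nitrogen in g, conductances in relative units (their
    absolute scale is arbitrary because the conduit bases are).
    """

    tree: TreeSpec
    V_x_tot: float
    V_sw_tot: float
    V_p_tot: float
    N_x_tot: float
    N_p_tot: float
    N_leaf_tot: float
    K_x_tot: float
    K_p_tot: float
    A_leaf: float
    method: str

    QUANTITIES = ("V_x_tot", "V_sw_tot", "V_p_tot", "N_x_tot", "N_p_tot",
                  "N_leaf_tot", "K_x_tot", "K_p_tot")


def _pow_integral(e: float, L: float, L0: float) -> float:
    """integral of x**e over [L0, L]."""
    if abs(e + 1.0) < 1e-12:
        return math.log(L / L0)
    return (L ** (e + 1) - L0 ** (e + 1)) / (e + 1)


def leaf_area(tree: TreeSpec) -> float:
    """Leaf area (m^2) proportional to basal sapwood area: C_ls * A_sw(base)."""
    d_base = diameter_at_distance(tree.L, tree.params)
    A_sw_mm, _ = sapwood_partition(d_base, tree)
    return float(A_sw_mm) * MM2_TO_M2 * tree.params.C_ls


def whole_tree_closed_form(tree: TreeSpec) -> WholeTreeSummary:
    """Evaluate the no-heartwood closed forms exactly.

    With ``n(x) = (L/x)**(delta*beta1)`` every total is an incomplete power
    integral; e.g. the xylem volume integrand ``n * A_x`` is constant in x.
    Raises :class:`ScenarioError` for a finite sapwood cap.
    """
    if tree.has_heartwood_cap:
        raise ScenarioError("closed forms require r_sw_max = inf")
    p, L, L0 = tree.params, tree.L, tree.L0
    db1 = p.delta * p.beta1

    # areas in mm^2 with x in m -> totals carry 1e-6 to SI
    Cx = p.alpha1 * p.gamma ** p.beta1 * MM2_TO_M2   # A_x(x) = Cx x^{db1} [m^2]
    Cp = p.alpha2 * p.gamma ** p.beta2 * MM2_TO_M2
    db2 = p.delta * p.beta2
    nfac = L ** db1  # n(x) = nfac * x^{-db1}

    V_x = Cx * nfac * (L - L0)
    V_p = Cp * nfac * _pow_integral(db2 - db1, L, L0)

    CNx = p.alpha3 * p.gamma ** p.beta3 / 100.0
    db3 = p.delta * p.beta3
    N_x = Cx * nfac * p.wood_density * CNx * _pow_integral(db3, L, L0) * 1e3

    CNp = p.alpha4 * p.gamma ** p.beta4 / 100.0
    db4 = p.delta * p.beta4
    N_p = Cp * nfac * p.phloem_density * CNp \
        * _pow_integral(db2 - db1 + db4, L, L0) * 1e3

    A_lf = Cx * nfac * p.C_ls            # = A_x(base) * C_ls
    N_leaf = A_lf * p.rho_SLA * p.rho_N_leaf / 100.0

    # relative conductances: 1/K = integral dx / k(x)
    Ckx = (p.alpha1 * p.alpha7 * p.alpha5 ** 2
           * p.gamma ** (p.beta1 + p.beta7 + 2 * p.beta5)) * MM2_TO_M2
    ex = p.delta * (p.beta7 + 2 * p.beta5)
    R_x = _pow_integral(-ex, L, L0) / (Ckx * nfac)

    Ckp = (p.alpha2 * p.alpha8 * p.alpha6 ** 2
           * p.gamma ** (p.beta2 + p.beta8 + 2 * p.beta6)) * MM2_TO_M2
    ep = db2 - db1 + p.delta * (p.beta8 + 2 * p.beta6)
    R_p = _pow_integral(-ep, L, L0) / (Ckp * nfac)

    return WholeTreeSummary(
        tree=tree, V_x_tot=V_x, V_sw_tot=V_x, V_p_tot=V_p,
        N_x_tot=N_x, N_p_tot=N_p, N_leaf_tot=N_leaf,
        K_x_tot=1.0 / R_x, K_p_tot=1.0 / R_p, A_leaf=A_lf,
        method="closed-form",
    )


def _numeric_once(tree: TreeSpec, n_grid: int) -> WholeTreeSummary:
    prof = axial_profiles(tree, n_grid=n_grid, spacing="log")
    x = prof.x
    V_sw = float(np.trapezoid(prof.A_sw_tot, x))
    V_x = float(np.trapezoid(prof.A_x_tot, x))
    V_p = float(np.trapezoid(prof.A_p_tot, x))
    N_x = float(np.trapezoid(prof.N_line_x, x))
    N_p = float(np.trapezoid(prof.N_line_p, x))
    R_x = float(np.trapezoid(1.0 / prof.k_x, x))
    R_p = float(np.trapezoid(1.0 / prof.k_p, x))
    A_lf = leaf_area(tree)
    N_leaf = A_lf * tree.params.rho_SLA * tree.params.rho_N_leaf / 100.0
    return WholeTreeSummary(
        tree=tree, V_x_tot=V_x, V_sw_tot=V_sw, V_p_tot=V_p,
        N_x_tot=N_x, N_p_tot=N_p, N_leaf_tot=N_leaf,
        K_x_tot=1.0 / R_x, K_p_tot=1.0 / R_p, A_leaf=A_lf,
        method="quadrature",
    )


def whole_tree_numeric(tree: TreeSpec, n_grid: int = 512,
                       rel_tol: float = 1e-4,
                       max_grid: int = 1 << 16) -> WholeTreeSummary:
    """Whole-tree totals by trapezoid quadrature of the axial profile.

    The grid is doubled until every quantity changes by less than
    ``rel_tol`` between refinements (error raised at ``max_grid``).
    Works for any heartwood scenario and matches the closed forms to well
    below 0.1% without heartwood.
    """
    prev = _numeric_once(tree, n_grid)
    n = n_grid
    while True:
        n *= 2
        cur = _numeric_once(tree, n)
        worst = max(
            abs(getattr(cur, q) - getattr(prev, q)) / abs(getattr(cur, q))
            for q in WholeTreeSummary.QUANTITIES
        )
        if worst < rel_tol:
            return cur
        if n >= max_grid:
            raise RuntimeError(
                f"quadrature did not reach rel_tol={rel_tol} by {n} points "
                f"(last change {worst:.2e})")
        prev = cur


@dataclass(frozen=True)
class ExponentFit:
    """Log-log fitted height scaling ``Q = prefactor * L**exponent``."""

    quantity: str
    prefactor: float
    exponent: float
    fit_range: tuple[float, float]
    n_heights: int


def height_grid(fit_range: tuple[float, float] = (1.0, 25.0),
                n_heights: int = 12) -> np.ndarray:
    lo, hi = fit_range
    return np.logspace(np.log10(lo), np.log10(hi), n_heights)


def summaries_over_heights(base: TreeSpec, heights,
                           numeric: bool | None = None) -> list[WholeTreeSummary]:
    """Whole-tree summaries for the same scenario across tree heights."""
    out = []
    for L in heights:
        tree = replace(base, L=float(L))
        if numeric is None:
            use_numeric = tree.has_heartwood_cap
        else:
            use_numeric = numeric
        out.append(whole_tree_numeric(tree) if use_numeric
                   else whole_tree_closed_form(tree))
    return out


def scaling_exponent(quantity: str, base: TreeSpec,
                     fit_range: tuple[float, float] = (1.0, 25.0),
                     n_heights: int = 12,
                     numeric: bool | None = None) -> ExponentFit:
    """Height-scaling exponent of one whole-tree quantity.

    Log-log OLS of the quantity against L over a log-spaced height grid.
    ``numeric=None`` picks quadrature automatically when heartwood is
    present and the closed forms otherwise.
    """
    if n_heights < 8:
        raise ValueError("need >= 8 heights")
    Ls = height_grid(fit_range, n_heights)
    summaries = summaries_over_heights(base, Ls, numeric=numeric)
    vals = np.array([getattr(s, quantity) for s in summaries])
    if np.any(vals <= 0):
        raise ValueError("quantity must be positive for a log-log fit")
    slope, pref = fit_loglog_exponent(Ls, vals)
    return ExponentFit(quantity=quantity, prefactor=pref, exponent=slope,
                       fit_range=(float(Ls[0]), float(Ls[-1])),
                       n_heights=n_heights)


# ---------------------------------------------------------------------------
# sensitivity sweep


@dataclass
class SensitivityEnvelope:
    """Pointwise min/max envelopes of height curves relative to a 10 m tree."""

    heights: np.ndarray
    reference_L: float
    quantities: tuple
    lo: dict          # quantity -> np.ndarray over heights
    hi: dict
    base_curve: dict
    n_draws: int
    seed: int


SWEEP_QUANTITIES = ("V_sw_tot", "V_p_tot", "N_x_tot", "N_p_tot",
                    "N_leaf_tot", "K_x_tot", "K_p_tot")


def _perturbed_params(p: ScalingParams, rng: np.random.Generator,
                      amplitude: float) -> ScalingParams:
    draw = lambda v: v * rng.uniform(1 - amplitude, 1 + amplitude)
    return p.with_(
        delta=draw(p.delta), beta1=draw(p.beta1), beta2=draw(p.beta2),
        beta3=draw(p.beta3), beta4=draw(p.beta4), beta5=draw(p.beta5),
        beta6=draw(p.beta6),
    )


def sensitivity_sweep(base: TreeSpec, n_draws: int = 1000, seed: int = 0,
                      heights=None, reference_L: float = 10.0,
                      amplitude: float = 0.25,
                      r_sw_range: tuple[float, float] = (0.02, 2.0),
                      r_sw_law: str = "log-uniform") -> SensitivityEnvelope:
    """Random sweep of the scaling exponents and the sapwood-depth cap.

    Exponents beta1-beta6 and delta are drawn independently and uniformly
    within ``amplitude`` (default 75-125%) of their base values; the sapwood
    depth cap is drawn on ``r_sw_range`` (log-uniform by default, linear via
    ``r_sw_law="uniform"``).  Every quantity's height curve is normalized to
    its own value at ``reference_L`` before the pointwise min/max envelopes
    are taken.
    """
    if n_draws < 1:
        raise ValueError("n_draws >= 1")
    if heights is None:
        heights = height_grid((1.0, 30.0), 10)
    heights = np.asarray(heights, dtype=float)
    rng = np.random.default_rng(seed)

    def curves(params: ScalingParams, r_sw: float) -> dict:
        spec = TreeSpec(params=params, L=reference_L, L0=base.L0,
                        r_sw_max=r_sw,
                        hw_nitrogen_fraction=base.hw_nitrogen_fraction)
        ref = whole_tree_numeric(spec, n_grid=256, rel_tol=1e-3)
        rows = {q: [] for q in SWEEP_QUANTITIES}
        for L in heights:
            s = whole_tree_numeric(replace(spec, L=float(L)),
                                   n_grid=256, rel_tol=1e-3)
            for q in SWEEP_QUANTITIES:
                rows[q].append(getattr(s, q) / getattr(ref, q))
        return {q: np.array(v) for q, v in rows.items()}

    base_curve = curves(base.params, base.r_sw_max)
    lo = {q: base_curve[q].copy() for q in SWEEP_QUANTITIES}
    hi = {q: base_curve[q].copy() for q in SWEEP_QUANTITIES}
    for _ in range(n_draws):
        p = _perturbed_params(base.params, rng, amplitude)
        if r_sw_law == "log-uniform":
            r_sw = float(np.exp(rng.uniform(*np.log(r_sw_range))))
        elif r_sw_law == "uniform":
            r_sw = float(rng.uniform(*r_sw_range))
        else:
            raise ValueError("r_sw_law must be 'log-uniform' or 'uniform'")
        c = curves(p, r_sw)
        for q in SWEEP_QUANTITIES:
            lo[q] = np.minimum(lo[q], c[q])
            hi[q] = np.maximum(hi[q], c[q])
    return SensitivityEnvelope(
        heights=heights, reference_L=reference_L,
        quantities=SWEEP_QUANTITIES, lo=lo, hi=hi,
        base_curve=base_curve, n_draws=n_draws, seed=seed,
    )
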