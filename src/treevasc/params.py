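"""Species scaling parameters and tree specifications.

The whole-tree model is built from power laws in two couplings:

* stem/branch taper, ``d = gamma * x**delta`` with ``x`` the distance from
  the apex in metres and ``d`` the diameter in millimetres, and
* tissue properties as power laws of diameter, ``P = alpha * d**beta``
  (xylem/phloem cross-sectional area in mm^2, nitrogen mass fractions in %,
  and relative conduit radius / conduit area fraction).

Bases for the conduit quantities are arbitrary: only relative axial
profiles of hydraulic conductivity enter any result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ScalingParams:
    """Power-law bases/exponents plus leaf constants for one species.

    Attributes
    ----------
    gamma, delta:
        Taper law ``d[mm] = gamma * x[m]**delta``.
    alpha1, beta1:
        Xylem cross-sectional area, mm^2 per mm^beta1.
    alpha2, beta2:
        Phloem (inner living bark) cross-sectional area, mm^2.
    alpha3, beta3:
        Xylem nitrogen mass fraction, %.
    alpha4, beta4:
        Phloem nitrogen mass fraction, %.
    alpha5, beta5 / alpha6, beta6:
        Xylem / phloem conduit radius (relative units).
    alpha7, beta7 / alpha8, beta8:
        Conduit lumen fraction of the tissue cross-section (relative units);
        ``beta7 = beta8 = 0`` encodes a size-independent lumen fraction.
    C_ls:
        Leaf area per basal sapwood area, m^2 m^-2.
    rho_SLA:
        Leaf dry mass per leaf area, g m^-2.
    rho_N_leaf:
        Leaf nitrogen mass fraction, %.
    wood_density, phloem_density:
        Tissue densities, kg m^-3; they convert nitrogen mass fractions into
        nitrogen amounts per volume and cancel in every scaling exponent.
    """

    name: str
    gamma: float
    delta: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    alpha3: float
    beta3: float
    alpha4: float
    beta4: float
    alpha5: float = 1.0
    beta5: float = 0.25
    alpha6: float = 1.0
    beta6: float = 0.25
    alpha7: float = 1.0
    beta7: float = 0.0
    alpha8: float = 1.0
    beta8: float = 0.0
    C_ls: float = 3400.0
    rho_SLA: float = 300.0
    rho_N_leaf: float = 1.2
    wood_density: float = 400.0
    phloem_density: float = 1000.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("area bases must be positive")

    def with_(self, **kwargs) -> "ScalingParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


PINE = ScalingParams(
    name="pine",
    gamma=15.8, delta=0.97,
    alpha1=0.82, beta1=1.98,
    alpha2=0.75, beta2=1.27,
    alpha3=2.02, beta3=-0.61,
    alpha4=1.4, beta4=-0.22,
    C_ls=3400.0, rho_SLA=300.0, rho_N_leaf=1.2,
)

ASPEN = ScalingParams(
    name="aspen",
    gamma=15.6, delta=0.97,
    alpha1=0.71, beta1=2.00,
    alpha2=0.99, beta2=1.31,
    alpha3=0.68, beta3=-0.34,
    alpha4=22.1, beta4=-0.80,
    C_ls=2700.0, rho_SLA=80.0, rho_N_leaf=2.4,
)

SPECIES = {"pine": PINE, "aspen": ASPEN}


# Per-species measured regressions P = B * d**E against diameter (mm), used
# by the synthetic generator.  "x_apex" is the distance from apex in mm as a
# function of diameter (the inverse of the taper law, which is how the
# harvest data were regressed).
MEASURED_REGRESSIONS = {
    "birch": {
        "A_b": (0.45, 1.60), "A_x": (0.67, 2.01), "A_p": (0.32, 1.59),
        "rho_N_x": (0.11, 0.21), "rho_N_p": (7.1, -0.59),
        "x_apex": (115.0, 1.00),
    },
    "pine": {
        "A_b": (0.38, 1.61), "A_x": (0.82, 1.98), "A_p": (0.75, 1.27),
        "rho_N_x": (2.02, -0.61), "rho_N_p": (1.4, -0.22),
        "x_apex": (61.0, 1.029),
    },
    "spruce": {
        "A_b": (0.52, 1.59), "A_x": (0.55, 2.05), "A_p": (0.0086, 2.35),
        "rho_N_x": (0.15, -0.021), "rho_N_p": (0.87, -0.10),
        "x_apex": (85.0, 0.98),
    },
    "aspen": {
        "A_b": (0.61, 1.53), "A_x": (0.71, 2.00), "A_p": (0.99, 1.30),
        "rho_N_x": (0.68, -0.34), "rho_N_p": (22.0, -0.79),
        "x_apex": (73.0, 1.05),
    },
}


@dataclass(frozen=True)
class TreeSpec:
    """One tree instance: species parameters, size and heartwood scenario.

    ``r_sw_max`` is the maximum sapwood depth in metres, measured radially
    inward from the xylem surface; ``math.inf`` means no heartwood ever
    forms.  ``hw_nitrogen_fraction`` is the heartwood nitrogen concentration
    as a fraction of the sapwood value (0 and 1 are the two bracketing
    scenarios; a literature mean across species is about 0.76).
    """

    params: ScalingParams
    L: float
    L0: float = 0.1
    r_sw_max: float = math.inf
    hw_nitrogen_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.L0 < self.L):
            raise ValueError("need 0 < L0 < L")
        if self.r_sw_max <= 0:
            raise ValueError("r_sw_max must be positive")
        if not (0.0 <= self.hw_nitrogen_fraction <= 1.0):
            raise ValueError("hw_nitrogen_fraction must be in [0, 1]")

    @property
    def has_heartwood_cap(self) -> bool:
        return math.isfinite(self.r_sw_max)
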