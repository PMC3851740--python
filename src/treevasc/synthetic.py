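"""Synthetic branch/stem measurement datasets.

The harvested-tree tables behind the allometries are not deposited anywhere,
so this module generates datasets with the same statistical structure:
diameters spanning the measured 0.9-276.2 mm range (log-uniform, because the
measured size distribution is strongly right-skewed), and every response
following its measured power law ``P = B * d**E`` times multiplicative
lognormal noise.  Refitting a generated dataset therefore recovers the
measured regression table up to sampling noise, and exactly in the
noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import MEASURED_REGRESSIONS

#: responses drawn as power laws of diameter, with per-response noise CVs
#: chosen so that ln-scale refits land in the R^2 ranges of the measured
#: regressions (areas ~0.94-0.999, nitrogen fractions ~0.7-0.9)
DEFAULT_NOISE_CV = {
    "A_x": 0.10,
    "A_b": 0.45,
    "A_p": 0.30,
    "rho_N_x": 0.40,
    "rho_N_p": 0.35,
    "x_apex": 0.30,
}

#: periderm (outer bark) nitrogen mass fraction used to mix the whole-bark
#: nitrogen column, % — synthetic plumbing, not a measured regression
PERIDERM_N_PERCENT = 0.4

COLUMNS = [
    "species", "d_over_bark", "d_under_bark", "A_x", "A_b", "A_p",
    "x_apex", "rho_N_x", "rho_N_p", "rho_N_bark",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic dataset.

    ``noise_cv`` may be a single coefficient of variation applied to every
    response or a per-response mapping (missing keys fall back to the
    defaults scaled to a common level when a scalar is given).
    """

    species: str = "pine"
    n_samples: int = 2000
    d_range: tuple[float, float] = (0.9, 276.2)
    noise_cv: float | dict = field(default_factory=lambda: dict(DEFAULT_NOISE_CV))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in MEASURED_REGRESSIONS:
            raise ValueError(f"unknown species {self.species!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.d_range
        if not (0 < lo < hi):
            raise ValueError("d_range must satisfy 0 < min < max")
        cvs = self.cv_map()
        if any(v < 0 for v in cvs.values()):
            raise ValueError("noise_cv must be >= 0")

    def cv_map(self) -> dict:
        if isinstance(self.noise_cv, dict):
            out = dict(DEFAULT_NOISE_CV)
            out.update(self.noise_cv)
            return out
        return {k: float(self.noise_cv) for k in DEFAULT_NOISE_CV}


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int):
    """Multiplicative noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size))


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one dataset of segment records as a DataFrame.

    Deterministic for a fixed seed.  Invariants enforced on every record:
    ``0 < d_under_bark < d_over_bark``, all areas positive, ``A_p <= A_b``,
    nitrogen fractions in (0, 100).
    """
    rng = np.random.default_rng(config.seed)
    reg = MEASURED_REGRESSIONS[config.species]
    cv = config.cv_map()
    n = config.n_samples
    lo, hi = config.d_range

    d = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    def draw(name):
        B, E = reg[name]
        return B * d ** E * _lognormal_factor(rng, cv[name], n)

    A_x = draw("A_x")
    A_b = draw("A_b")
    A_p = draw("A_p")
    x_apex = draw("x_apex")
    rho_N_x = np.clip(draw("rho_N_x"), 1e-4, 99.0)
    rho_N_p = np.clip(draw("rho_N_p"), 1e-4, 99.0)

    # consistency: the whole bark must contain its living bark.  The fitted
    # laws cross at small diameters, so the (descriptive, downstream-unused)
    # whole-bark column absorbs the clip; the under-bark diameter follows
    # from the bark annulus (floored so a noisy bark draw can never swallow
    # the whole section).
    A_b = np.maximum(A_b, A_p)
    ratio_sq = np.clip(1.0 - (4.0 / np.pi) * A_b / d ** 2, 0.01, 1.0 - 1e-6)
    d_under = d * np.sqrt(ratio_sq)

    peri = np.clip(A_b - A_p, 0.0, None)
    rho_N_bark = (A_p * rho_N_p + peri * PERIDERM_N_PERCENT) / A_b

    return pd.DataFrame({
        "species": config.species,
        "d_over_bark": d,
        "d_under_bark": d_under,
        "A_x": A_x,
        "A_b": A_b,
        "A_p": A_p,
        "x_apex": x_apex,
        "rho_N_x": rho_N_x,
        "rho_N_p": rho_N_p,
        "rho_N_bark": rho_N_bark,
    })[COLUMNS]


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    """Write a segment table as CSV (one record per row, documented header)."""
    df.to_csv(path, index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df
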