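"""Rosenthal-Henderson theory: particle-number limit and B-factor fitting.

The minimum number of particle images needed to reach resolution d is

    N_particles = (1 / N_asym) * ((S/N)^2 * 30 pi / (N_e sigma_e d))
                  * exp(B / (2 d^2))

with N_asym the number of asymmetric units per particle, S/N = 1/sqrt(3)
the signal-to-noise threshold equivalent to a 60 deg phase error (the
FSC = 0.143 half-map criterion), N_e = 5 e-/A^2 the limiting dose for
near-atomic features, sigma_e = 0.004 A^2 the elastic cross-section of
carbon at 300 kV, and B the overall temperature factor summarizing every
resolution-limiting property of the instrument (50 A^2 for a standard
Titan Krios).

The B-factor of a dataset is estimated from a series of reconstructions at
particle counts N_i reaching resolutions d_i by ordinary least squares of
ln N against 1/d^2; the fitted slope is B/2 (the classical
Rosenthal-Henderson plot, which drops the slowly varying 1/d prefactor; a
flag restores it as a ln(1/d) offset).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "LimitParams",
    "BFactorFitResult",
    "symmetry_order",
    "theoretical_particle_limit",
    "fold_of_limit",
    "fit_rh_bfactor",
    "round_half_up",
]

_SNR_DEFAULT = 1.0 / math.sqrt(3.0)


@dataclass
class LimitParams:
    """Inputs of the particle-number limit, with the standard defaults."""

    n_asym: int = 1
    resolution_A: float = 3.0  # d
    b_factor_A2: float = 50.0  # B
    snr_threshold: float = _SNR_DEFAULT  # S/N
    dose_e_per_A2: float = 5.0  # N_e
    sigma_e_A2: float = 0.004  # elastic cross-section of carbon

    def __post_init__(self) -> None:
        vals = (self.n_asym, self.resolution_A, self.b_factor_A2,
                self.snr_threshold, self.dose_e_per_A2, self.sigma_e_A2)
        if any(v <= 0 for v in vals):
            raise ValueError("all limit parameters must be positive")


@dataclass
class BFactorFitResult:
    b_factor_A2: float
    intercept: float
    points: List[Tuple[float, float]]  # (n_particles, resolution_A)


_SYM_RE = re.compile(r"^([CD])(\d+)$|^([TOI])$", re.IGNORECASE)


def symmetry_order(symbol: str) -> int:
    """Number of asymmetric units of a point-group symbol.

    Cn -> n, Dn -> 2n, T -> 12, O -> 24, I -> 60.
    """
    m = _SYM_RE.match(symbol.strip())
    if not m:
        raise ValueError(f"unknown symmetry symbol {symbol!r}")
    if m.group(3):
        return {"T": 12, "O": 24, "I": 60}[m.group(3).upper()]
    n = int(m.group(2))
    if n < 1:
        raise ValueError(f"invalid symmetry order in {symbol!r}")
    return n if m.group(1).upper() == "C" else 2 * n


def theoretical_particle_limit(params: LimitParams) -> float:
    """Minimum particle count to reach ``params.resolution_A`` (unrounded)."""
    d = params.resolution_A
    snr2 = params.snr_threshold**2
    prefactor = snr2 * 30.0 * math.pi / (params.dose_e_per_A2
                                         * params.sigma_e_A2 * d)
    return (prefactor / params.n_asym) * math.exp(
        params.b_factor_A2 / (2.0 * d * d)
    )


def round_half_up(x: float) -> int:
    """Table-style integer rounding (0.5 always rounds up)."""
    return int(math.floor(x + 0.5))


def fold_of_limit(n_particles: float, params: LimitParams) -> float:
    """How many times a stack exceeds its theoretical limit (one decimal)."""
    if not n_particles > 0:
        raise ValueError("n_particles must be positive")
    return round(n_particles / theoretical_particle_limit(params), 1)


def fit_rh_bfactor(
    points: Sequence[Tuple[float, float]],
    include_d_prefactor: bool = False,
) -> BFactorFitResult:
    """Fit the Rosenthal-Henderson B-factor from (n_particles, resolution)
    pairs: OLS of ln N (minus ln(1/d) when the prefactor correction is
    requested) against 1/d^2; B is twice the slope. Repeated points (e.g.
    from half-splitting repetitions) enter the fit jointly."""
    pts = [(float(n), float(d)) for n, d in points]
    if len(pts) < 2 or len({d for _, d in pts}) < 2:
        raise ValueError("need >= 2 points with distinct resolutions")
    if any(n <= 0 or d <= 0 for n, d in pts):
        raise ValueError("particle counts and resolutions must be positive")
    x = np.array([1.0 / (d * d) for _, d in pts])
    y = np.array([math.log(n) for n, _ in pts])
    if include_d_prefactor:
        y = y - np.array([math.log(1.0 / d) for _, d in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return BFactorFitResult(b_factor_A2=2.0 * float(slope),
                            intercept=float(intercept), points=pts)
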