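"""Acceptance-probability laws for worsening moves.

At high temperatures the classical Boltzmann law exp(−ΔE/T) governs
acceptance.  At low temperatures bosonic systems condense into their
lowest-energy states, and the Bose-Einstein occupation
1/(e^λ · e^(ΔE/T) − 1) is used instead (Boltzmann's constant absorbed
into T so that temperature carries energy units).  With λ = 0 the two
laws are linked algebraically: BE = B/(1 − B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcceptanceParams",
    "boltzmann_prob",
    "bose_einstein_prob",
    "accept",
]


@dataclass(frozen=True)
class AcceptanceParams:
    """Which law to apply and its parameters.

    ``lambda_be`` is the particle-number Lagrange multiplier of the
    Bose-Einstein occupation; the analytical tuning formulas assume
    λ = 0, which is the default.  ``clamp`` saturates raw occupation
    values above 1 to a probability of 1 (raw BE exceeds 1 whenever
    λ + ΔE/T < ln 2).
    """

    distribution: str = "boltzmann"
    lambda_be: float = 0.0
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.distribution not in ("boltzmann", "bose_einstein"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not math.isfinite(self.lambda_be):
            raise ValueError("lambda_be must be finite")


def boltzmann_prob(delta: float, T: float) -> float:
    """exp(−ΔE/T) for a worsening move ΔE > 0 at temperature T > 0."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    return math.exp(-delta / T)


def bose_einstein_prob(
    delta: float, T: float, params: AcceptanceParams | None = None
) -> float:
    """Bose-Einstein acceptance 1/(e^λ · e^(ΔE/T) − 1), clamped to [0, 1].

    With ``params.clamp`` disabled the raw occupation is returned, which
    exceeds 1 for λ + ΔE/T < ln 2.
    """
    p = params or AcceptanceParams(distribution="bose_einstein")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    exponent = p.lambda_be + delta / T
    if exponent == 0:
        raise ValueError("singular denominator: lambda + delta/T = 0")
    if exponent > 700:  # e^x overflows; occupation is numerically 0
        return 0.0
    raw = 1.0 / (math.exp(exponent) - 1.0)
    if p.clamp:
        return min(raw, 1.0)
    return raw


def accept(
    delta: float,
    T: float,
    params: AcceptanceParams,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Metropolis decision: improvements always pass; worsening moves pass
    with the law's probability against a single uniform draw.

    Returns (accepted, uniform) where uniform is the draw consumed (NaN
    when no draw was needed), enabling bitwise replay of full runs.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if delta <= 0:
        return True, math.nan
    if params.distribution == "boltzmann":
        prob = boltzmann_prob(delta, T)
    else:
        prob = bose_einstein_prob(delta, T, params)
    u = float(rng.uniform())
    return prob > u, u
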