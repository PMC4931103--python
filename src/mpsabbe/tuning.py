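"""Analytical tuning of the annealing schedule.

Every schedule parameter is derived in closed form from the extremes of
sampled deterioration (the positive energy increases ΔZ of random
perturbations):

* initial temperature — the T at which a move of maximal deterioration
  ΔZ_max is accepted with a chosen high probability (inverting the
  acceptance law);
* final temperature — the T at which the minimal deterioration ΔZ_min
  survives only with a chosen small probability;
* step count n — from the cooling law connecting the two temperatures;
* Markov-chain growth β — so the metropolis length grows geometrically
  from L1 to L_max over exactly n temperature steps, with
  L_max = ⌈C·|V|⌉ set by the neighborhood size and the exploration
  constant C = −ln(1 − P_reject), C ∈ [1, 4.6].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conformation import AngleRanges, perturb, random_conformation
from .energy import EnergyModel

__all__ = [
    "DeteriorationSample",
    "Schedule",
    "sample_deterioration",
    "initial_temperature_boltzmann",
    "final_temperature_boltzmann",
    "initial_temperature_bose_einstein",
    "final_temperature_bose_einstein",
    "n_steps_geometric",
    "n_steps_exponential",
    "metropolis_growth",
    "exploration_constant",
    "max_metropolis_length",
    "phase_boundaries",
    "build_schedule",
]


@dataclass(frozen=True)
class DeteriorationSample:
    """Extremes of positive energy increases over sampled move pairs."""

    delta_max: float
    delta_min: float
    sample_size: int

    def __post_init__(self) -> None:
        if not 0 < self.delta_min <= self.delta_max:
            raise ValueError("need 0 < delta_min <= delta_max")


@dataclass(frozen=True)
class Schedule:
    """The full tuned parameter set of a four-phase run."""

    T_initial: float
    T_fMQP: float
    T_fBAP: float
    T_fBEAP: float
    T_final: float
    alpha_annealing: float = 0.95
    n_steps: int = 1
    L1: int = 1
    L_max: int = 1
    beta: float = 1.0
    C: float = 3.0
    accept_p_max: float = 0.95
    accept_p_min: float = 0.01

    def __post_init__(self) -> None:
        temps = (self.T_initial, self.T_fMQP, self.T_fBAP, self.T_fBEAP, self.T_final)
        if not all(a > b for a, b in zip(temps, temps[1:])) or temps[-1] <= 0:
            raise ValueError(
                "phase temperatures must be strictly decreasing and positive: "
                f"{temps}"
            )
        if self.beta < 1.0:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not 1 <= self.L1 <= self.L_max:
            raise ValueError("need 1 <= L1 <= L_max")
        if not 1.0 <= self.C <= 4.6:
            raise ValueError(f"C must be in [1, 4.6], got {self.C}")


def sample_deterioration(
    energy: EnergyModel,
    sequence: str | None = None,
    n_samples: int = 200,
    seed: int = 0,
    ranges: AngleRanges | None = None,
    box: tuple[float, float] = (0.0, 360.0),
) -> DeteriorationSample:
    """Extremes of positive ΔZ over ``n_samples`` random (state, perturbed) pairs.

    For a protein model pass ``sequence``; states are Ramachandran-valid
    random conformations and single-angle perturbations.  For vector
    benchmarks states are uniform in ``box`` with one coordinate redrawn.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    positives = []
    for _ in range(n_samples):
        if sequence is not None:
            current = random_conformation(sequence, ranges, rng)
            proposed = perturb(current, ranges, rng=rng)
        else:
            current = rng.uniform(box[0], box[1], size=energy.dimension)
            proposed = current.copy()
            proposed[int(rng.integers(energy.dimension))] = rng.uniform(*box)
        d = energy(proposed) - energy(current)
        if d > 0:
            positives.append(d)
    if not positives:
        raise ValueError(
            "no positive deterioration observed; increase n_samples or check "
            "that the energy model is non-constant"
        )
    return DeteriorationSample(
        delta_max=float(max(positives)),
        delta_min=float(min(positives)),
        sample_size=n_samples,
    )


def initial_temperature_boltzmann(delta_max: float, p: float) -> float:
    """T at which exp(−ΔZ_max/T) = p:  T = −ΔZ_max / ln p."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    return -delta_max / math.log(p)


def final_temperature_boltzmann(delta_min: float, p: float) -> float:
    """T at which the minimal worsening survives with probability p."""
    return initial_temperature_boltzmann(delta_min, p)


def initial_temperature_bose_einstein(delta_max: float, p: float) -> float:
    """T at which 1/(e^(ΔZ_max/T) − 1) = p:  T = ΔZ_max / ln((p+1)/p).

    Unlike the Boltzmann inverse, p = 1 is admissible (it forces
    e^(ΔZ/T) = 2, a finite temperature).
    """
    if p <= 0:
        raise ValueError(f"p must be positive, got {p}")
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    return delta_max / math.log((p + 1.0) / p)


def final_temperature_bose_einstein(delta_min: float, p: float) -> float:
    return initial_temperature_bose_einstein(delta_min, p)


def n_steps_geometric(T_initial: float, T_final: float, alpha: float) -> int:
    """Smallest n with α^n·T_initial ≤ T_final:  ⌈(ln T_f − ln T_i)/ln α⌉."""
    if not 0 < T_final < T_initial:
        raise ValueError("need 0 < T_final < T_initial")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ratio = (math.log(T_final) - math.log(T_initial)) / math.log(alpha)
    n = math.ceil(ratio - 1e-9)  # guard the exact-integer case against fp noise
    return max(n, 1)


def n_steps_exponential(T_initial: float, T_final: float, alpha: float) -> int:
    """Smallest n with e^(−nα)·T_initial ≤ T_final:  ⌈(ln T_i − ln T_f)/α⌉."""
    if not 0 < T_final < T_initial:
        raise ValueError("need 0 < T_final < T_initial")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    n = math.ceil((math.log(T_initial) - math.log(T_final)) / alpha - 1e-9)
    return max(n, 1)


def metropolis_growth(L1: int, L_max: int, n: int) -> float:
    """β with L1·β^n = L_max:  β = exp((ln L_max − ln L1)/n)."""
    if L1 < 1 or L_max < L1:
        raise ValueError("need 1 <= L1 <= L_max")
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.exp((math.log(L_max) - math.log(L1)) / n)


def exploration_constant(rejection_p: float) -> float:
    """C = −ln(1 − P_reject), clipped to [1, 4.6].

    The printed exploration levels (63% → 1, 86% → 2, 95% → 3,
    99% → 4.6) follow this complement form.
    """
    if not 0 < rejection_p < 1:
        raise ValueError(f"rejection_p must be in (0, 1), got {rejection_p}")
    return min(max(-math.log(1.0 - rejection_p), 1.0), 4.6)


def max_metropolis_length(neighborhood_size: int, rejection_p: float = 0.95) -> int:
    """L_max = ⌈C · |V|⌉ for neighborhood size |V| and exploration level C."""
    if neighborhood_size < 1:
        raise ValueError("neighborhood_size must be >= 1")
    return math.ceil(exploration_constant(rejection_p) * neighborhood_size)


def phase_boundaries(
    T_initial: float,
    T_final: float,
    fractions: tuple[float, float, float] = (1e-1, 1e-3, 1e-5),
) -> tuple[float, float, float]:
    """Intermediate phase temperatures T_fMQP > T_fBAP > T_fBEAP.

    Each boundary is placed at T_initial times the given fraction so the
    phases span decades of temperature.  When T_final is too close to
    T_initial for those decades to fit, the boundaries fall back to
    geometric (log-uniform) interpolation at the quartiles of the log
    range, which always satisfies the strict ordering.
    """
    if not 0 < T_final < T_initial:
        raise ValueError("need 0 < T_final < T_initial")
    cands = tuple(T_initial * f for f in fractions)
    chain = (T_initial, *cands, T_final)
    if all(a > b for a, b in zip(chain, chain[1:])):
        return cands
    log_i, log_f = math.log(T_initial), math.log(T_final)
    return tuple(
        math.exp(log_i + q * (log_f - log_i)) for q in (0.25, 0.5, 0.75)
    )


def build_schedule(
    deterioration: DeteriorationSample,
    neighborhood_size: int,
    alpha_annealing: float = 0.95,
    accept_p_max: float = 0.95,
    accept_p_min: float = 0.01,
    rejection_p: float = 0.95,
    L1: int = 1,
    distribution: str = "boltzmann",
    L_max_cap: int | None = None,
    boundary_fractions: tuple[float, float, float] = (1e-1, 1e-3, 1e-5),
) -> Schedule:
    """Assemble the full Schedule from sampled deterioration.

    ``distribution`` picks which acceptance law's inverse sets the
    temperature endpoints.  ``L_max_cap`` optionally bounds the maximal
    metropolis length (useful when |V| is very large).
    """
    if distribution == "boltzmann":
        T_i = initial_temperature_boltzmann(deterioration.delta_max, accept_p_max)
        T_f = final_temperature_boltzmann(deterioration.delta_min, accept_p_min)
    elif distribution == "bose_einstein":
        T_i = initial_temperature_bose_einstein(deterioration.delta_max, accept_p_max)
        T_f = final_temperature_bose_einstein(deterioration.delta_min, accept_p_min)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    if T_f >= T_i:
        raise ValueError(
            f"tuning produced T_final {T_f} >= T_initial {T_i}; "
            "widen the design probabilities or resample deterioration"
        )
    T_mqp, T_bap, T_beap = phase_boundaries(T_i, T_f, boundary_fractions)
    L_max = max_metropolis_length(neighborhood_size, rejection_p)
    if L_max_cap is not None:
        L_max = min(L_max, max(L_max_cap, L1))
    n = n_steps_geometric(T_i, T_f, alpha_annealing)
    beta = metropolis_growth(L1, L_max, n)
    return Schedule(
        T_initial=T_i,
        T_fMQP=T_mqp,
        T_fBAP=T_bap,
        T_fBEAP=T_beap,
        T_final=T_f,
        alpha_annealing=alpha_annealing,
        n_steps=n,
        L1=L1,
        L_max=L_max,
        beta=beta,
        C=exploration_constant(rejection_p),
        accept_p_max=accept_p_max,
        accept_p_min=accept_p_min,
    )
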