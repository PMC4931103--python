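"""Temperature-update laws.

Three classical cooling functions — geometric T' = αT, exponential
T' = e^(−α)T, Lundy-Mees T' = T/(1 + ηT) — plus the multiquench law
T' = α_quench · (1 − τ) · T, where τ starts near 1 and is squared each
step (τ' = τ²).  When τ crosses its floor a new quench subphase begins
and τ resets, so within a subphase cooling accelerates from a near-total
quench toward the plain geometric limit T' = α_quench·T.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["CoolingSpec", "QuenchState", "cool", "quench_step"]


@dataclass(frozen=True)
class CoolingSpec:
    """One of the classical cooling laws with its parameter."""

    law: str = "geometric"
    alpha: float = 0.95
    eta: float = 0.01  # Lundy-Mees only

    def __post_init__(self) -> None:
        if self.law not in ("geometric", "exponential", "lundy"):
            raise ValueError(f"unknown cooling law {self.law!r}")
        if self.law == "geometric" and not 0.7 <= self.alpha < 1.0:
            raise ValueError(
                f"geometric alpha must be in [0.7, 1.0), got {self.alpha}"
            )
        if self.law == "exponential" and self.alpha <= 0:
            raise ValueError("exponential alpha must be positive")
        if self.law == "lundy" and self.eta <= 0:
            raise ValueError("lundy eta must be positive")


@dataclass(frozen=True)
class QuenchState:
    """Mutable part of the multiquench schedule: current τ and subphase."""

    alpha_quenching: float = 0.85
    tau: float = 0.999
    tau_initial: float = 0.999
    tau_floor: float = 0.001
    subphase_index: int = 0

    def __post_init__(self) -> None:
        if not 0.7 <= self.alpha_quenching <= 1.0:
            raise ValueError(
                f"alpha_quenching must be in [0.7, 1.0], got {self.alpha_quenching}"
            )
        if not 0 < self.tau_floor < self.tau_initial < 1:
            raise ValueError("need 0 < tau_floor < tau_initial < 1")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


def cool(T: float, spec: CoolingSpec) -> float:
    """Apply one classical cooling step; strictly decreases T."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if spec.law == "geometric":
        return spec.alpha * T
    if spec.law == "exponential":
        import math

        return math.exp(-spec.alpha) * T
    return T / (1.0 + spec.eta * T)


def quench_step(
    T: float, state: QuenchState, gamma_mode: str = "as_printed"
) -> tuple[float, QuenchState]:
    """One multiquench update: T' = α_q·γ·T, then τ' = τ² with floor reset.

    ``gamma_mode`` selects γ = 1 − τ (the literal quench law, default) or
    γ = τ (the gentle complement, for sensitivity studies).  The update
    uses the state's current τ; the squared τ is carried in the returned
    state, resetting to ``tau_initial`` (and advancing the subphase) once
    it falls to ``tau_floor`` or below.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if gamma_mode not in ("as_printed", "complement"):
        raise ValueError(f"unknown gamma_mode {gamma_mode!r}")
    gamma = (1.0 - state.tau) if gamma_mode == "as_printed" else state.tau
    T_next = state.alpha_quenching * gamma * T
    tau_next = state.tau * state.tau
    if tau_next <= state.tau_floor:
        next_state = replace(
            state, tau=state.tau_initial, subphase_index=state.subphase_index + 1
        )
    else:
        next_state = replace(state, tau=tau_next)
    return T_next, next_state
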