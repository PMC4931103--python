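"""The four annealing phases and the classical-SA baseline.

A run chains four phases over a strictly decreasing temperature ladder:

* MQP  — multiquench: very fast τ-modulated cooling from the extremely
  hot end, short fixed metropolis cycles, Boltzmann acceptance;
* BAP  — Boltzmann annealing: geometric cooling with metropolis cycles
  growing geometrically (L' = βL) up to L_max;
* BEAP — Bose-Einstein annealing: constant cycles of length L_max with
  Bose-Einstein acceptance;
* DEP  — dynamical-equilibrium phase: Bose-Einstein acceptance at the
  cold end, stopping when the least-squares slope of energy against
  iteration over a trailing window flattens.

Each phase starts from the best solution of the previous one and at the
temperature where the previous phase ended.  Every proposal is logged,
including the uniform draw consumed by the acceptance decision, so a
complete run replays bitwise from its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .acceptance import AcceptanceParams, accept
from .conformation import AngleRanges, Conformation, perturb, random_conformation
from .cooling import QuenchState, quench_step
from .tuning import Schedule

__all__ = [
    "TraceRecord",
    "RunTrace",
    "PhaseResult",
    "AnnealingProblem",
    "conformation_problem",
    "vector_problem",
    "EquilibriumWindow",
    "slope",
    "slope_constants",
    "run_mqp",
    "run_bap",
    "run_beap",
    "run_dep",
    "run_classical_sa",
    "run_mpsabbe",
]


class TraceRecord(NamedTuple):
    iteration: int
    phase: str
    subphase: int
    temperature: float
    current_energy: float
    proposal_energy: float
    accepted: bool
    law: str
    uniform: float  # NaN when the decision needed no draw


RunTrace = list  # list[TraceRecord]


@dataclass
class PhaseResult:
    best_state: object
    best_energy: float
    end_temperature: float
    iterations_used: int
    trace: list[TraceRecord]
    stop_reason: str = "temperature_floor"

    @property
    def best_conformation(self) -> object:
        return self.best_state


@dataclass(frozen=True)
class AnnealingProblem:
    """State space for the optimizer: energy plus a proposal kernel."""

    energy: Callable[[object], float]
    propose: Callable[[object, np.random.Generator], object]
    initial_state: Callable[[np.random.Generator], object]
    dimension: int
    neighborhood_size: int


def conformation_problem(
    sequence: str,
    energy: Callable[[Conformation], float],
    ranges: AngleRanges | None = None,
    n_moves: int = 1,
) -> AnnealingProblem:
    """Dihedral-space problem: states are Ramachandran-valid conformations."""
    from .conformation import count_variables

    ranges = ranges or AngleRanges()
    dim = count_variables(sequence)
    per_step = int(round(360.0 / ranges.step_granularity))
    return AnnealingProblem(
        energy=energy,
        propose=lambda c, rng: perturb(c, ranges, n_moves=n_moves, rng=rng),
        initial_state=lambda rng: random_conformation(sequence, ranges, rng),
        dimension=dim,
        neighborhood_size=dim * per_step,
    )


def vector_problem(
    energy: Callable[[np.ndarray], float],
    dimension: int,
    box: tuple[float, float] = (0.0, 360.0),
    step: float = 1.0,
) -> AnnealingProblem:
    """Box-constrained vector problem on a uniform grid.

    Proposals redraw one coordinate uniformly on the grid, matching the
    dihedral move kernel; used for the analytic benchmark landscapes.
    """
    lo, hi = box
    n_grid = int(round((hi - lo) / step))

    def propose(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.array(x)
        y[int(rng.integers(dimension))] = lo + step * int(rng.integers(n_grid))
        return y

    return AnnealingProblem(
        energy=energy,
        propose=propose,
        initial_state=lambda rng: lo + step * rng.integers(n_grid, size=dimension).astype(float),
        dimension=dimension,
        neighborhood_size=dimension * n_grid,
    )


# ---------------------------------------------------------------------------
# equilibrium detection


def slope_constants(n: int, printed: bool = False) -> tuple[float, float]:
    """(k1, k2) of the running-sum slope m = k1·Σ i·E_i − k2·Σ E_i.

    ``printed=True`` returns k2 = 6/(n² + n), a transcription that fails
    the exact-line check (E_i = i must give slope 1); the default uses
    the algebraically correct k2 = 6/(n² − n).
    """
    if n < 3:
        raise ValueError("window length must be >= 3")
    k1 = 12.0 / (n**3 - n)
    k2 = 6.0 / (n**2 + n) if printed else 6.0 / (n**2 - n)
    return k1, k2


def slope(energies: Sequence[float], printed_k2: bool = False) -> float:
    """O(n) least-squares slope of E against iteration index 1…n."""
    e = np.asarray(energies, dtype=float)
    n = e.size
    k1, k2 = slope_constants(n, printed=printed_k2)
    i = np.arange(1, n + 1)
    return float(k1 * np.dot(i, e) - k2 * e.sum())


@dataclass(frozen=True)
class EquilibriumWindow:
    """Trailing energy window with its running-sum slope."""

    energies: tuple[float, ...]
    slope_tolerance: float = 1e-3

    @property
    def n(self) -> int:
        return len(self.energies)

    @property
    def m(self) -> float:
        return slope(self.energies)

    @property
    def at_equilibrium(self) -> bool:
        return abs(self.m) < self.slope_tolerance


# ---------------------------------------------------------------------------
# inner metropolis machinery


class _Runner:
    """Shared proposal/acceptance loop with trace bookkeeping."""

    def __init__(
        self,
        problem: AnnealingProblem,
        state: object,
        rng: np.random.Generator,
        start_iteration: int = 0,
    ):
        self.problem = problem
        self.state = state
        self.energy = float(problem.energy(state))
        self.best_state = state
        self.best_energy = self.energy
        self.rng = rng
        self.iteration = start_iteration
        self.trace: list[TraceRecord] = []

    def step(self, T: float, phase: str, subphase: int, params: AcceptanceParams) -> None:
        proposal = self.problem.propose(self.state, self.rng)
        e_new = float(self.problem.energy(proposal))
        delta = e_new - self.energy
        ok, u = accept(delta, T, params, self.rng)
        self.iteration += 1
        if ok:
            self.state = proposal
            self.energy = e_new
            if e_new < self.best_energy:
                self.best_energy = e_new
                self.best_state = proposal
        self.trace.append(
            TraceRecord(
                self.iteration, phase, subphase, T,
                self.energy, e_new, ok, params.distribution, u,
            )
        )

    def result(self, end_T: float, stop_reason: str = "temperature_floor") -> PhaseResult:
        return PhaseResult(
            best_state=self.best_state,
            best_energy=self.best_energy,
            end_temperature=end_T,
            iterations_used=len(self.trace),
            trace=self.trace,
            stop_reason=stop_reason,
        )


_BOLTZ = AcceptanceParams("boltzmann")


# ---------------------------------------------------------------------------
# phases


def run_mqp(
    start: object,
    schedule: Schedule,
    problem: AnnealingProblem,
    quench: QuenchState | None = None,
    rng: np.random.Generator | int = 0,
    gamma_mode: str = "as_printed",
    start_iteration: int = 0,
) -> PhaseResult:
    """Multiquench phase: T_initial → T_fMQP under the τ-quench law.

    Fixed metropolis cycles of length L1, Boltzmann acceptance.  The
    cooled temperature is clamped at T_fMQP so the next phase starts
    exactly at the phase boundary.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    quench = quench or QuenchState()
    runner = _Runner(problem, start, rng, start_iteration)
    T = schedule.T_initial
    while T > schedule.T_fMQP:
        for _ in range(schedule.L1):
            runner.step(T, "MQP", quench.subphase_index, _BOLTZ)
        T_next, quench = quench_step(T, quench, gamma_mode)
        T = max(T_next, schedule.T_fMQP)
    return runner.result(schedule.T_fMQP)


def run_bap(
    start: object,
    schedule: Schedule,
    problem: AnnealingProblem,
    rng: np.random.Generator | int = 0,
    start_iteration: int = 0,
) -> PhaseResult:
    """Boltzmann annealing: T_fMQP → T_fBAP, metropolis length L' = βL."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    runner = _Runner(problem, start, rng, start_iteration)
    T = schedule.T_fMQP
    k = 0
    while True:
        # L_k = L1·β^k in closed form (an incremental product drifts);
        # the cycle at the floor temperature is included so the last
        # metropolis cycle reaches L_max when β was tuned for the phase
        L = min(round(schedule.L1 * schedule.beta**k), schedule.L_max)
        for _ in range(max(L, 1)):
            runner.step(T, "BAP", 0, _BOLTZ)
        if T <= schedule.T_fBAP:
            break
        k += 1
        T = max(schedule.alpha_annealing * T, schedule.T_fBAP)
    return runner.result(schedule.T_fBAP)


def run_beap(
    start: object,
    schedule: Schedule,
    problem: AnnealingProblem,
    rng: np.random.Generator | int = 0,
    lambda_be: float = 0.0,
    start_iteration: int = 0,
) -> PhaseResult:
    """Bose-Einstein annealing: T_fBAP → T_fBEAP, constant length L_max."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    params = AcceptanceParams("bose_einstein", lambda_be=lambda_be)
    runner = _Runner(problem, start, rng, start_iteration)
    T = schedule.T_fBAP
    while T > schedule.T_fBEAP:
        for _ in range(schedule.L_max):
            runner.step(T, "BEAP", 0, params)
        T = max(schedule.alpha_annealing * T, schedule.T_fBEAP)
    return runner.result(schedule.T_fBEAP)


def run_dep(
    start: object,
    schedule: Schedule,
    problem: AnnealingProblem,
    rng: np.random.Generator | int = 0,
    window_n: int = 100,
    tolerance: float = 1e-3,
    iteration_cap: int = 100_000,
    hold_temperature: bool = False,
    lambda_be: float = 0.0,
    start_iteration: int = 0,
) -> PhaseResult:
    """Dynamical-equilibrium phase: Bose-Einstein acceptance at the cold end.

    Anneals from T_fBEAP down to T_final (or holds at T_final when
    ``hold_temperature``), cooling once per L_max proposals.  After each
    proposal beyond ``window_n`` the least-squares slope of the trailing
    ``window_n`` energies is checked; |slope| < tolerance stops the phase
    (stop_reason "equilibrium"), otherwise the iteration cap fires.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    params = AcceptanceParams("bose_einstein", lambda_be=lambda_be)
    runner = _Runner(problem, start, rng, start_iteration)
    T = schedule.T_final if hold_temperature else schedule.T_fBEAP
    window: list[float] = []
    count = 0
    stop = "iteration_cap"
    while count < iteration_cap:
        runner.step(T, "DEP", 0, params)
        count += 1
        window.append(runner.energy)
        if len(window) > window_n:
            window.pop(0)
            if abs(slope(window)) < tolerance:
                stop = "equilibrium"
                break
        if not hold_temperature and count % schedule.L_max == 0:
            T = max(schedule.alpha_annealing * T, schedule.T_final)
    return runner.result(T, stop)


def run_classical_sa(
    start: object,
    problem: AnnealingProblem,
    T_initial: float,
    T_final: float,
    alpha: float = 0.95,
    metropolis_length: int = 50,
    rng: np.random.Generator | int = 0,
    max_proposals: int | None = None,
) -> PhaseResult:
    """Single-loop geometric-cooling SA with Boltzmann acceptance."""
    if not 0 < T_final < T_initial:
        raise ValueError("need 0 < T_final < T_initial")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    runner = _Runner(problem, start, rng)
    T = T_initial
    stop = "temperature_floor"
    while T > T_final:
        for _ in range(metropolis_length):
            runner.step(T, "CLASSICAL", 0, _BOLTZ)
            if max_proposals is not None and len(runner.trace) >= max_proposals:
                return runner.result(T, "proposal_budget")
        T *= alpha
    return runner.result(T, stop)


def run_mpsabbe(
    problem: AnnealingProblem,
    schedule: Schedule,
    seed: int = 0,
    start: object | None = None,
    quench: QuenchState | None = None,
    gamma_mode: str = "as_printed",
    dep_window: int = 100,
    dep_tolerance: float = 1e-3,
    dep_cap: int = 100_000,
    dep_hold_temperature: bool = False,
    lambda_be: float = 0.0,
) -> PhaseResult:
    """Full four-phase run: MQP → BAP → BEAP → DEP.

    Each phase consumes its own RNG stream derived from (seed, phase
    index), starts from the previous phase's best solution, and resumes
    at the temperature boundary the previous phase reached.  Returns the
    merged trace and the overall best solution.
    """
    def phase_rng(i: int) -> np.random.Generator:
        return np.random.default_rng([seed, i])

    state = (
        start if start is not None else problem.initial_state(phase_rng(0))
    )
    r_mqp = run_mqp(
        state, schedule, problem, quench, phase_rng(1), gamma_mode
    )
    it = r_mqp.iterations_used
    r_bap = run_bap(
        r_mqp.best_state, schedule, problem, phase_rng(2), start_iteration=it
    )
    it += r_bap.iterations_used
    r_beap = run_beap(
        r_bap.best_state, schedule, problem, phase_rng(3),
        lambda_be=lambda_be, start_iteration=it,
    )
    it += r_beap.iterations_used
    r_dep = run_dep(
        r_beap.best_state, schedule, problem, phase_rng(4),
        window_n=dep_window, tolerance=dep_tolerance,
        iteration_cap=dep_cap, hold_temperature=dep_hold_temperature,
        lambda_be=lambda_be, start_iteration=it,
    )
    results = (r_mqp, r_bap, r_beap, r_dep)
    best = min(results, key=lambda r: r.best_energy)
    trace: list[TraceRecord] = []
    for r in results:
        trace.extend(r.trace)
    return PhaseResult(
        best_state=best.best_state,
        best_energy=best.best_energy,
        end_temperature=r_dep.end_temperature,
        iterations_used=len(trace),
        trace=trace,
        stop_reason=r_dep.stop_reason,
    )
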