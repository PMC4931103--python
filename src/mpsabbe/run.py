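"""High-level run orchestration: configuration → tuned schedule → full run.

This is the glue the command-line interface calls: it builds the problem
(protein sequence with the simplified force field, or a benchmark
landscape), samples deterioration, derives the schedule analytically,
applies explicit overrides, and executes either the four-phase optimizer
or the classical-SA baseline.  Runs are pure functions of
(configuration, root seed): repeating one reproduces the trace bitwise.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from .conformation import AngleRanges
from .cooling import QuenchState
from .energy import MemoizedEnergy, benchmark_model, protein_model
from .phases import (
    AnnealingProblem,
    PhaseResult,
    conformation_problem,
    run_classical_sa,
    run_mpsabbe,
    vector_problem,
)
from .tuning import Schedule, build_schedule, sample_deterioration

__all__ = ["build_problem", "tune_from_config", "fold", "baseline"]

_SCHEDULE_KEYS = (
    "T_initial", "T_fMQP", "T_fBAP", "T_fBEAP", "T_final",
    "alpha_annealing", "n_steps", "L1", "L_max", "beta", "C",
    "accept_p_max", "accept_p_min",
)


def build_problem(config: dict[str, Any]) -> AnnealingProblem:
    """Problem from config: 'sequence' selects the protein model,
    'energy' one of the benchmark landscapes (with 'dimension')."""
    sequence = config.get("sequence")
    energy_name = config.get("energy", "simplified_forcefield")
    if sequence:
        model = MemoizedEnergy(protein_model(sequence))
        ranges = AngleRanges(
            step_granularity=float(config.get("step_granularity", 1.0))
        )
        return conformation_problem(
            sequence, model, ranges, n_moves=int(config.get("n_moves", 1))
        )
    dimension = int(config.get("dimension", 2))
    model = benchmark_model(energy_name, dimension)
    return vector_problem(
        model,
        dimension,
        step=float(config.get("step_granularity", 1.0)),
    )


def tune_from_config(
    config: dict[str, Any], problem: AnnealingProblem, seed: int
) -> Schedule:
    """Analytically tuned schedule, then explicit config overrides."""
    det = sample_deterioration(
        _model_for(problem, config),
        sequence=config.get("sequence"),
        n_samples=int(config.get("n_deterioration_samples", 200)),
        seed=seed,
    )
    schedule = build_schedule(
        det,
        neighborhood_size=problem.neighborhood_size,
        alpha_annealing=float(config.get("alpha_annealing", 0.95)),
        accept_p_max=float(config.get("accept_p_max", 0.95)),
        accept_p_min=float(config.get("accept_p_min", 0.01)),
        rejection_p=float(config.get("rejection_p", 0.95)),
        L1=int(config.get("L1", 1)),
        distribution=config.get("tuning_distribution", "boltzmann"),
        L_max_cap=(
            int(config["L_max_cap"]) if "L_max_cap" in config else None
        ),
    )
    overrides = {k: config[k] for k in _SCHEDULE_KEYS if k in config}
    if overrides:
        schedule = replace(schedule, **overrides)
    return schedule


def _model_for(problem: AnnealingProblem, config: dict[str, Any]):
    """Deterioration sampling needs an EnergyModel-shaped object."""
    class _Shim:
        dimension = problem.dimension

        def __call__(self, state):
            return problem.energy(state)

    return _Shim()


def fold(config: dict[str, Any], seed: int) -> tuple[PhaseResult, Schedule]:
    """Full four-phase run from a configuration and root seed."""
    problem = build_problem(config)
    schedule = tune_from_config(config, problem, seed)
    quench = QuenchState(
        alpha_quenching=float(config.get("alpha_quenching", 0.85)),
        tau=float(config.get("tau_initial", 0.999)),
        tau_initial=float(config.get("tau_initial", 0.999)),
        tau_floor=float(config.get("tau_floor", 0.001)),
    )
    result = run_mpsabbe(
        problem,
        schedule,
        seed=seed,
        quench=quench,
        gamma_mode=config.get("gamma_mode", "as_printed"),
        dep_window=int(config.get("dep_window", 100)),
        dep_tolerance=float(config.get("dep_tolerance", 1e-3)),
        dep_cap=int(config.get("dep_cap", 100_000)),
        dep_hold_temperature=bool(config.get("dep_hold_temperature", False)),
        lambda_be=float(config.get("lambda", 0.0)),
    )
    return result, schedule


def baseline(
    config: dict[str, Any], seed: int, max_proposals: int | None = None
) -> tuple[PhaseResult, Schedule]:
    """Classical-SA comparison run under the same tuned temperatures."""
    problem = build_problem(config)
    schedule = tune_from_config(config, problem, seed)
    rng = np.random.default_rng([seed, 0])
    start = problem.initial_state(rng)
    result = run_classical_sa(
        start,
        problem,
        schedule.T_initial,
        schedule.T_final,
        alpha=schedule.alpha_annealing,
        metropolis_length=int(config.get("metropolis_length", schedule.L_max)),
        rng=np.random.default_rng([seed, 1]),
        max_proposals=max_proposals,
    )
    return result, schedule
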