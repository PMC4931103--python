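"""Phase runners, slope detector, full-chain behavior and replay audit."""

import math

import numpy as np
import pytest

from mpsabbe import (
    QuenchState,
    benchmark_model,
    boltzmann_prob,
    bose_einstein_prob,
    run_bap,
    run_beap,
    run_classical_sa,
    run_dep,
    run_mpsabbe,
    run_mqp,
    slope,
    vector_problem,
)
from mpsabbe.acceptance import AcceptanceParams
from mpsabbe.cooling import quench_step
from mpsabbe.energy import EnergyModel
from mpsabbe.phases import EquilibriumWindow, slope_constants


def flat_problem(dim=2):
    return vector_problem(EnergyModel("flat", lambda x: 0.0, dim), dim)


def sphere_problem(dim=2):
    model = benchmark_model("sphere", dim)
    return vector_problem(model, dim, box=(-5.0, 5.0), step=0.01)


def rugged_problem(dim=2):
    return vector_problem(benchmark_model("rugged_torsion", dim), dim)


class TestSlope:
    def test_exact_line(self):
        assert slope([3.0, 5.0, 7.0]) == pytest.approx(2.0, abs=1e-12)

    def test_constant_window(self):
        assert slope([4.0] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_unit_slope_identity(self):
        for n in (3, 10, 50):
            assert slope(list(range(1, n + 1))) == pytest.approx(1.0, abs=1e-9)

    def test_printed_k2_fails_the_exact_line_check(self):
        """The transcribed constant k2 = 6/(n²+n) does not reproduce the
        slope of E_i = i; the corrected 6/(n²−n) does."""
        e = list(range(1, 11))
        assert slope(e, printed_k2=True) != pytest.approx(1.0, abs=1e-3)
        assert slope(e) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_two_pass_least_squares(self):
        """100 random windows: the running-sum form equals the textbook
        two-pass fit to 1e-9 relative."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            e = rng.normal(size=n) * 10
            x = np.arange(1, n + 1)
            expected = float(np.polyfit(x, e, 1)[0])
            assert slope(e) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            slope([1.0, 2.0])

    def test_equilibrium_window_object(self):
        w = EquilibriumWindow(tuple(float(i) for i in range(1, 8)), 1e-3)
        assert w.n == 7 and w.m == pytest.approx(1.0, abs=1e-12)
        assert not w.at_equilibrium
        assert EquilibriumWindow((1.0, 1.0, 1.0)).at_equilibrium

    def test_constants(self):
        k1, k2 = slope_constants(3)
        assert k1 == pytest.approx(12 / 24) and k2 == pytest.approx(6 / 6)


class TestMqp:
    def test_flat_landscape_accepts_everything(self, small_schedule):
        r = run_mqp(np.zeros(2), small_schedule, flat_problem(), rng=0)
        assert all(rec.accepted for rec in r.trace)
        assert r.best_energy == 0.0

    def test_bitwise_determinism(self, small_schedule):
        p = sphere_problem()
        s0 = p.initial_state(np.random.default_rng(5))
        r1 = run_mqp(s0, small_schedule, p, rng=np.random.default_rng(1))
        r2 = run_mqp(s0, small_schedule, p, rng=np.random.default_rng(1))
        assert r1.trace == r2.trace
        assert r1.best_energy == r2.best_energy

    def test_temperature_sequence_replays_quench_recurrence(self, small_schedule):
        """Logged MQP temperatures reproduce an independent iteration of
        the quench law from T_initial, clamped at the phase floor."""
        r = run_mqp(np.zeros(2), small_schedule, flat_problem(), rng=0)
        expected = []
        T, state = small_schedule.T_initial, QuenchState()
        while T > small_schedule.T_fMQP:
            expected.extend([T] * small_schedule.L1)
            T_next, state = quench_step(T, state)
            T = max(T_next, small_schedule.T_fMQP)
        assert [rec.temperature for rec in r.trace] == expected
        assert r.end_temperature == small_schedule.T_fMQP

    def test_uses_boltzmann_law(self, small_schedule):
        r = run_mqp(np.zeros(2), small_schedule, rugged_problem(), rng=3)
        assert {rec.law for rec in r.trace} == {"boltzmann"}


class TestBap:
    def test_metropolis_lengths_grow_geometrically(self):
        """Lengths follow L1·β^k (rounded) and the final cycle is within
        one of L_max when β was tuned for the phase's step count."""
        from mpsabbe.tuning import Schedule, metropolis_growth, n_steps_geometric

        Ti, Tf, alpha = 10.0, 0.1, 0.9
        n = n_steps_geometric(Ti, Tf, alpha)
        L1, Lmax = 2, 40
        beta = metropolis_growth(L1, Lmax, n)
        sched = Schedule(
            T_initial=100.0, T_fMQP=Ti, T_fBAP=Tf, T_fBEAP=0.01, T_final=0.001,
            alpha_annealing=alpha, n_steps=n, L1=L1, L_max=Lmax, beta=beta,
        )
        r = run_bap(np.zeros(2), sched, flat_problem(), rng=0)
        # group proposals by temperature step
        temps = [rec.temperature for rec in r.trace]
        uniq = sorted(set(temps), reverse=True)
        lengths = [temps.count(t) for t in uniq]
        expected = [min(round(L1 * beta**k), Lmax) for k in range(len(uniq))]
        assert lengths == expected
        assert abs(lengths[-1] - Lmax) <= 1
        assert len(uniq) == n + 1  # both endpoint temperatures included

    def test_improves_on_rugged_landscape(self, small_schedule):
        """Median best over seeds strictly below the median initial energy
        (sign test at 1%: all 20 of 20 runs improving is far beyond it)."""
        p = rugged_problem()
        improved = 0
        for seed in range(20):
            s0 = p.initial_state(np.random.default_rng([seed, 0]))
            e0 = p.energy(s0)
            r = run_bap(s0, small_schedule, p, rng=np.random.default_rng([seed, 1]))
            improved += r.best_energy < e0
        # one-sided binomial: P(X >= 15 | p=0.5, n=20) < 0.01
        assert improved >= 15

    def test_boltzmann_law_used(self, small_schedule):
        r = run_bap(np.zeros(2), small_schedule, rugged_problem(), rng=1)
        assert {rec.law for rec in r.trace} == {"boltzmann"}


class TestBeap:
    def test_constant_inner_length(self, small_schedule):
        r = run_beap(np.zeros(2), small_schedule, rugged_problem(), rng=2)
        temps = [rec.temperature for rec in r.trace]
        for t in set(temps):
            assert temps.count(t) % small_schedule.L_max == 0

    def test_hot_limit_accepts_everything(self):
        from mpsabbe.tuning import Schedule

        sched = Schedule(
            T_initial=1e9, T_fMQP=1e8, T_fBAP=1e7, T_fBEAP=1e6 + 1, T_final=1.0,
            alpha_annealing=0.9, L1=1, L_max=10, beta=1.0,
        )
        r = run_beap(np.zeros(2), sched, rugged_problem(), rng=4)
        assert all(rec.accepted for rec in r.trace)

    def test_bose_einstein_law_used(self, small_schedule):
        r = run_beap(np.zeros(2), small_schedule, rugged_problem(), rng=2)
        assert {rec.law for rec in r.trace} == {"bose_einstein"}


class TestDep:
    def test_flat_landscape_stops_after_window_plus_one(self, small_schedule):
        r = run_dep(np.zeros(2), small_schedule, flat_problem(), rng=0, window_n=50)
        assert r.iterations_used == 51
        assert r.stop_reason == "equilibrium"

    def test_decreasing_stream_defers_termination(self, small_schedule):
        """A strictly decreasing energy stream with slope −1 must not trip
        a 0.1 tolerance until it flattens."""
        values = iter([float(1000 - i) for i in range(400)] + [600.0] * 400)

        class Stream:
            def __call__(self, x):
                return next(values)

        p = vector_problem(EnergyModel("stream", Stream(), 1), 1)
        r = run_dep(
            np.zeros(1), small_schedule, p, rng=0,
            window_n=50, tolerance=0.1, iteration_cap=800,
        )
        assert r.stop_reason == "equilibrium"
        assert r.iterations_used > 350  # not before the plateau

    def test_detector_matches_offline_slope_replay(self, small_schedule):
        """DEP's stopping decision coincides with an offline pass of the
        slope oracle over every trailing window of the logged energies."""
        p = rugged_problem()
        r = run_dep(
            p.initial_state(np.random.default_rng(8)), small_schedule, p,
            rng=9, window_n=40, tolerance=1e-3, iteration_cap=2000,
        )
        energies = [rec.current_energy for rec in r.trace]
        first_hit = None
        for i in range(41, len(energies) + 1):
            w = energies[i - 40: i]
            if abs(float(np.polyfit(np.arange(1, 41), w, 1)[0])) < 1e-3:
                first_hit = i
                break
        if r.stop_reason == "equilibrium":
            assert first_hit == len(energies)
        else:
            assert first_hit is None

    def test_iteration_cap_fires(self, small_schedule):
        p = sphere_problem()
        r = run_dep(
            p.initial_state(np.random.default_rng(1)), small_schedule, p,
            rng=1, window_n=100, tolerance=0.0, iteration_cap=300,
        )
        assert r.stop_reason == "iteration_cap"
        assert r.iterations_used == 300

    def test_hold_temperature_option(self, small_schedule):
        r = run_dep(
            np.zeros(2), small_schedule, flat_problem(), rng=0,
            window_n=20, hold_temperature=True,
        )
        assert {rec.temperature for rec in r.trace} == {small_schedule.T_final}


class TestClassicalSa:
    def test_greedy_limit_never_worsens(self):
        p = sphere_problem()
        s0 = p.initial_state(np.random.default_rng(2))
        r = run_classical_sa(s0, p, T_initial=1e-9 * 2, T_final=1e-9, alpha=0.4999,
                             metropolis_length=200, rng=3)
        assert r.best_energy <= p.energy(s0)
        final_currents = [rec.current_energy for rec in r.trace]
        assert final_currents[-1] <= final_currents[0]

    def test_bitwise_determinism(self):
        p = rugged_problem()
        s0 = p.initial_state(np.random.default_rng(0))
        r1 = run_classical_sa(s0, p, 100.0, 0.01, rng=np.random.default_rng(5))
        r2 = run_classical_sa(s0, p, 100.0, 0.01, rng=np.random.default_rng(5))
        assert r1.trace == r2.trace

    def test_converges_on_sphere(self):
        """Generous schedule on the 2-d sphere: nearly all seeded runs end
        within 1e-2 of the optimum."""
        p = sphere_problem()
        hits = 0
        for seed in range(20):
            s0 = p.initial_state(np.random.default_rng([seed, 0]))
            r = run_classical_sa(
                s0, p, T_initial=10.0, T_final=1e-6, alpha=0.9,
                metropolis_length=60, rng=np.random.default_rng([seed, 1]),
            )
            hits += r.best_energy < 1e-2
        assert hits >= 18

    def test_budget_cutoff(self):
        p = sphere_problem()
        r = run_classical_sa(
            p.initial_state(np.random.default_rng(0)), p, 100.0, 0.01,
            metropolis_length=50, rng=1, max_proposals=73,
        )
        assert r.iterations_used == 73
        assert r.stop_reason == "proposal_budget"


class TestFullChain:
    def test_phase_order_and_continuity(self, small_schedule):
        r = run_mpsabbe(rugged_problem(), small_schedule, seed=3, dep_window=40,
                        dep_cap=500)
        order = []
        for rec in r.trace:
            if not order or order[-1] != rec.phase:
                order.append(rec.phase)
        assert order == ["MQP", "BAP", "BEAP", "DEP"]

    def test_running_minimum_is_monotone(self, small_schedule):
        r = run_mpsabbe(rugged_problem(), small_schedule, seed=5, dep_window=40,
                        dep_cap=500)
        best = math.inf
        for rec in r.trace:
            best = min(best, rec.current_energy)
        assert r.best_energy == pytest.approx(best)

    def test_overall_best_below_each_phase_start(self, small_schedule):
        r = run_mpsabbe(rugged_problem(), small_schedule, seed=7, dep_window=40,
                        dep_cap=500)
        starts = {}
        for rec in r.trace:
            starts.setdefault(rec.phase, rec.current_energy)
        assert all(r.best_energy <= e for e in starts.values())

    def test_acceptance_decisions_replay_from_trace(self, small_schedule):
        """Full-run audit: every logged decision is reproducible from
        (δ, T, law, logged uniform)."""
        r = run_mpsabbe(rugged_problem(), small_schedule, seed=11, dep_window=40,
                        dep_cap=500)
        checked = 0
        for k, rec in enumerate(r.trace):
            phase_start = k == 0 or r.trace[k - 1].phase != rec.phase
            if phase_start:
                if rec.accepted:
                    # pre-decision energy is not recoverable from this
                    # record alone; skip (at most one record per phase)
                    continue
                energy_before = rec.current_energy
            else:
                energy_before = r.trace[k - 1].current_energy
            delta = rec.proposal_energy - energy_before
            if delta <= 0:
                assert rec.accepted and math.isnan(rec.uniform)
            else:
                p = (
                    boltzmann_prob(delta, rec.temperature)
                    if rec.law == "boltzmann"
                    else bose_einstein_prob(
                        delta, rec.temperature, AcceptanceParams("bose_einstein")
                    )
                )
                assert rec.accepted == (p > rec.uniform)
            checked += 1
        assert checked >= len(r.trace) - 4
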