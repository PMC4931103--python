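# mpsabbe

Multiphase simulated annealing with **Boltzmann and Bose-Einstein
acceptance distributions**, applied to protein conformational search in
dihedral-angle space.

Classical simulated annealing accepts a worsening move of size ΔE at
temperature T with the Boltzmann probability exp(−ΔE/T) at every stage
of the cooling. At low temperature, however, bosonic systems condense
into their lowest-energy states, and the Bose-Einstein occupation

    P(ΔE, T) = 1 / (e^λ · e^(ΔE/T) − 1)        (λ = 0 by default)

is the natural acceptance law. This package implements a four-phase
optimizer that switches law as the system cools:

| phase | temperature range | cooling | acceptance |
|-------|-------------------|---------|------------|
| MQP  (multiquench)            | extremely high → high | T′ = α_q(1 − τ)T, τ′ = τ² | Boltzmann |
| BAP  (Boltzmann annealing)    | high → low            | T′ = αT, cycles grow L′ = βL | Boltzmann |
| BEAP (Bose-Einstein annealing)| low → very low        | T′ = αT, constant cycles L_max | Bose-Einstein |
| DEP  (dynamical equilibrium)  | very low → final      | T′ = αT then hold | Bose-Einstein |

DEP stops itself: after every proposal it fits the least-squares slope
m = k₁·Σ i·Eᵢ − k₂·Σ Eᵢ (k₁ = 12/(n³−n), k₂ = 6/(n²−n)) of the energy
over a trailing window and terminates when |m| falls below a tolerance —
the signature of stochastic equilibrium.

Every schedule parameter is derived analytically from the sampled
extremes of deterioration ΔZ (the positive energy increases of random
moves): T_initial = −ΔZ_max/ln P(ΔZ_max) under the Boltzmann law (or
ΔZ_max/ln((P+1)/P) under Bose-Einstein), T_final likewise from ΔZ_min,
the step count n = ⌈ln(T_f/T_i)/ln α⌉, the Markov-length growth
β = exp((ln L_max − ln L₁)/n), and L_max = ⌈C·|V|⌉ with the exploration
constant C = −ln(1 − P_reject) ∈ [1, 4.6].

The protein state is the vector of backbone and side-chain torsions
(φ, ψ, ω, χ per residue) with ω fixed at 180°, φ restricted to
[180°, 300°] ∪ [45°, 60°] and ψ to [20°, 205°] ∪ [300°, 330°]
(Ramachandran-allowed regions). Energies come from a simplified
ECEPP-style backbone force field (6-12 Lennard-Jones, Coulomb
electrostatics, cosine torsions, 12-10 hydrogen bond); analytic
benchmark landscapes (sphere, Rastrigin, a rugged periodic torsion
surface) with exhaustively groundable optima validate the optimizer
itself. A classical single-loop SA baseline and the two-sample
statistics used to compare replicate runs round out the toolkit.

## Worked example

Compare two experimental arms (mean, sd, n = 30 replicate runs each) and
test whether the new optimizer found lower energies on the packaged
pentapeptide tables:

```python
from mpsabbe import GroupSummary, two_sample_t, improvement_percent
from mpsabbe.io import fixture_table

ta, tb = fixture_table("mpsabbe"), fixture_table("cmqa")
a = GroupSummary("met", ta.loc["met_enkephalin", "energy_mean"],
                 ta.loc["met_enkephalin", "energy_sd"], 30)
b = GroupSummary("met", tb.loc["met_enkephalin", "energy_mean"],
                 tb.loc["met_enkephalin", "energy_sd"], 30)
r = two_sample_t(a, b)
print(f"t = {r.t_statistic:.4f}  critical = {r.critical_value}  reject_null = {r.reject_null}")
print(f"improvement = {improvement_percent(a.mean, b.mean):.2f}%")
```

prints

```
t = -2.6367  critical = 1.645  reject_null = False
improvement = 13.74%
```

t is far below the one-sided critical value, so the hypothesis that the
multiphase optimizer's mean energy exceeds the reference's is rejected:
it found lower energies, by 13.74% of the reference mean.

Run the optimizer itself on the rugged torsion benchmark (d = 2, whose
global optimum an exhaustive 1° grid search puts at −0.050251):

```python
from mpsabbe.run import fold

cfg = dict(energy="rugged_torsion", dimension=2, L_max_cap=60,
           dep_cap=3000, dep_window=100, dep_tolerance=1e-3,
           alpha_annealing=0.9)
r, s = fold(cfg, seed=1)
print(f"best energy {r.best_energy:.6f} after {r.iterations_used} proposals "
      f"(stop: {r.stop_reason})")
```

prints

```
best energy -0.050251 after 2852 proposals (stop: equilibrium)
```

— the four-phase run reaches the grid optimum and DEP's slope detector,
not an iteration budget, ends it.

A CLI mirrors this: `mpsabbe tune|fold|baseline` take `--fasta`,
`--config` (flat YAML, keys named after the schedule symbols:
`alpha_annealing`, `tau_initial`, `L1`, `L_max`, `C`, …) and `--seed`,
and write the trace CSV, schedule JSON and a PDB of the best backbone;
`mpsabbe stats` compares two run-summary CSVs.

## Limitations

The packaged force field reuses the ECEPP functional families over the
four backbone atom types only; its absolute energies are on its own
scale and are not comparable to published full-force-field values.
Superposition RMSD is Kabsch-optimal over CA atoms (no structural
alignment search). See `docs/methods.md` for the model details, the
parameter defaults and the numerical choices.
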