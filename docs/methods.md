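# Methods

## State space and moves

A conformation is the vector of dihedral angles of an amino-acid chain:
per residue φ, ψ, ω and the side-chain torsions χ₁…χ_k, all in degrees
on [0, 360). ω is pinned at 180° (trans peptide bond). φ is sampled
from [180°, 300°] ∪ [45°, 60°] and ψ from [20°, 205°] ∪ [300°, 330°] —
the ψ windows [20°, 180°] and [180°, 205°] overlap, and the union is
the only consistent reading. χ angles are unrestricted; the number of
χ variables per residue follows the standard rotamer counts (0 for
Gly/Ala up to 4 for Lys/Arg). Terminal residues keep their full
φ/ψ/ω triple as variables even though residue 1's φ and ω and the last
residue's ψ have no geometric effect; the uniform rule makes the
variable count reproducible: the pentapeptide YGGFM has 3·5 + (2+0+0+2+3)
= 22 variables under this convention. (Published variable counts for
the same peptide differ — e.g. 19 — because χ-counting conventions vary
and are rarely printed; the packaged table is the convention here.)

Angles live on a uniform grid, 1°/step by default (configurable). The
default move kernel redraws one uniformly chosen non-ω angle uniformly
within its allowed intervals; a bounded `move_width` restricts the
redraw to a window around the current value with rejection sampling.
Moves never mutate their input; every randomized operation is a pure
function of (inputs, seed), so whole runs replay bitwise.

## Geometry

Backbone N/CA/C coordinates are built by sequential natural extension
(each atom placed from the previous three by bond length, bond angle,
torsion), which is exactly invertible: torsions measured from the built
coordinates reproduce the inputs to ≤ 1e-4° (tested at ~1e-13°).
Bond lengths/angles default to standard peptide values (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; 111.2°, 116.2°, 121.7°), overridable. The
carbonyl O is placed in the sp² plane of C(i) anti to N(i+1) — needed
only so PDB output is chemically sensible. RMSD is Kabsch-optimal
superposition (via SciPy's rotation alignment) over CA atoms by
default; the residual is recomputed from the rotated coordinates
because the solver's reported residual loses precision for
near-congruent sets. No structural-alignment search (TM-score style)
is attempted.

## Energy models

The protein energy keeps the ECEPP functional families over the four
backbone atom types N, CA, C, O:

* 6-12 Lennard-Jones with Lorentz-Berthelot combination;
* Coulomb electrostatics, constant dielectric (default 2);
* cosine torsion terms E = (V/2)(1 + cos(nθ − γ)) per angle class,
  including χ (ω's stiff 2-fold term keeps the trans state preferred);
* a 12-10 hydrogen bond replacing Lennard-Jones on nonbonded N···O
  pairs.

Pairs separated by 1–2 or 1–3 bonds are skipped; 1–4 pairs are scaled
(default 0.5). Pair distances are clamped at 0.1 Å so degenerate
conformations stay finite. The parameter set is small and packaged;
it is a test harness for the optimizer, and its absolute energies are
not comparable to any published force field. Energies are memoized per
state within a run (the phases re-evaluate the current solution's
energy constantly). The Boltzmann constant is absorbed into T, so
temperature carries energy units in both acceptance laws.

Benchmark landscapes: `sphere` (Σx²), `rastrigin`
(10d + Σ(x² − 10cos 2πx)), and `rugged_torsion` — per-coordinate
three-well terms 1 + cos(3x·π/180) plus weak pairwise coupling
0.1·cos((xᵢ−xⱼ)·π/180) over angles in degrees. In d = 2 its global
optimum is grounded by exhaustive 1° grid search (360² evaluations,
recomputed at test time, ≈ −0.050251 at (61°, 299°)).

## Acceptance laws

Boltzmann: P = exp(−ΔE/T). Bose-Einstein: P = 1/(e^λ·e^(ΔE/T) − 1)
with λ = 0 by default — the analytical tuning assumes λ = 0, under
which the two laws satisfy BE = B/(1 − B) exactly. The raw
Bose-Einstein occupation exceeds 1 whenever λ + ΔE/T < ln 2; it is
clamped to 1 (behaviorally "always accept"), with an unclamped variant
for the algebraic identities. Each decision consumes exactly one
uniform draw (none when ΔE ≤ 0), and the draw is logged in the trace,
which is what makes the full-run acceptance audit possible.

## Cooling and the quench law

Classical laws: geometric T′ = αT (α ∈ [0.7, 1)), exponential
T′ = e^(−α)T, Lundy-Mees T′ = T/(1 + ηT). The multiquench law is
T′ = α_q·(1 − τ)·T with τ′ = τ², τ₀ = 0.999, α_q = 0.85; when τ ≤ 0.001
it resets to τ₀ and a new subphase begins (13 squarings per subphase —
a frozen regression value). The literal γ = 1 − τ reading makes the
first multiplier ≈ 0.85·0.001, i.e. a ~1000× temperature drop — that is
the printed law and the default (`gamma_mode = "as_printed"`); the
gentle complement γ = τ is available for sensitivity studies. Because
the quench overshoots the phase floor, every phase clamps its end
temperature at its boundary so phase k+1 starts exactly where phase k
ended, preserving the temperature-ladder contract.

## Analytical tuning

From a seeded sample of (state, perturbed) pairs (default 200), the
extremes of positive deterioration give ΔZ_max and ΔZ_min. Then:

* T_initial = −ΔZ_max/ln P_hot (Boltzmann) or ΔZ_max/ln((P+1)/P)
  (Bose-Einstein; note P = 1 is admissible there, unlike Boltzmann —
  the printed form of the Bose-Einstein inverse is typographically
  ambiguous, and the algebraic inverse of the acceptance law is used);
* T_final likewise from ΔZ_min with P_cold;
* defaults P_hot = 0.95, P_cold = 0.01 (conventional hot/cold design
  probabilities; exposed in config);
* n = ⌈(ln T_f − ln T_i)/ln α⌉ (geometric) or ⌈(ln T_i − ln T_f)/α⌉
  (exponential), with a 1e-9 guard so exact-integer ratios don't round
  up on float noise;
* β = exp((ln L_max − ln L₁)/n), so L₁·βⁿ = L_max to 1e-9 relative;
* L_max = ⌈C·|V|⌉, C = −ln(1 − P_reject) clipped to [1, 4.6]. The
  complement form is the one consistent with the canonical exploration
  levels (63% → 1, 86% → 2, 95% → 3, 99% → 4.6). |V| for the dihedral
  problem is approximated as variable count × grid points per angle
  (360/step), which makes L_max large for real chains; `L_max_cap`
  bounds it for budgeted runs.

Intermediate phase boundaries (named T_fMQP > T_fBAP > T_fBEAP) are
placed at T_initial × {1e-1, 1e-3, 1e-5} so the phases span decades;
when T_final is too close for those decades to fit, they fall back to
log-uniform quartiles of [T_final, T_initial], which always satisfies
the strict ordering. Both the fractions and every schedule field are
overridable in config.

## Phases

MQP runs fixed cycles of length L₁ under the quench law with Boltzmann
acceptance. BAP cools geometrically with cycle lengths L_k = L₁·β^k
(computed in closed form — an incremental product drifts) capped at
L_max, including the cycle at the floor temperature so the last cycle
reaches L_max when β was tuned for the phase. BEAP runs constant
cycles of L_max with Bose-Einstein acceptance. DEP continues with
Bose-Einstein acceptance, cooling once per L_max proposals down to
T_final (optionally holding at T_final throughout); after each proposal
beyond the window length it evaluates the running-sum slope
m = k₁·Σ i·Eᵢ − k₂·Σ Eᵢ over the trailing window and stops when
|m| < tolerance, else at a hard cap. Defaults: window 100, tolerance
1e-3 energy-units/iteration, cap 1e5 — none are canonical; all
configurable. On a constant landscape DEP therefore stops after
exactly window + 1 proposals.

k₂ is 6/(n² − n), not the sometimes-printed 6/(n² + n): expanding the
two-pass least-squares slope with xᵢ = 1…n forces the former, and the
latter fails the exact-line check (Eᵢ = i must give slope 1). A
regression test asserts both facts.

Each phase starts from the previous phase's *best-found* solution (not
its last current one) and consumes an RNG stream derived from (root
seed, phase index), so phases are independently replayable. The driver
returns the merged trace; the classical baseline is a single
geometric-cooling Boltzmann loop over the same machinery, with an
optional proposal budget for matched comparisons.

## Comparison statistics

Replicate arms are summarized as (mean, sample sd with n−1, n) and
compared with t = (μ_a − μ_b)/√(s_a²/n_a + s_b²/n_b) against the
one-sided critical value 1.645 (normal 5% quantile; an exact Student-t
quantile with df = 2n − 2 is available but non-default). The packaged
summary tables carry n = 30 per arm — the unique replicate count under
which every tabulated t statistic reproduces from the printed means and
sds, which also confirms the n−1 sd convention. Improvement is
100·(μ_ref − μ_new)/|μ_ref|. Two of the published improvement
percentages for the larger chains do not follow from their own table
means under this (or any affine) formula and are treated as
irreproducible; the two small-protein figures reproduce to well within
rounding.

## Problem sizes used in tests and the acceptance script

The optimizer checks run the rugged-torsion benchmark in d = 4 for the
four-phase-versus-classical comparison (20 seeded pairs at matched
proposal budgets, ~2–6k proposals per run via `L_max_cap = 60`,
`dep_cap = 3000`) and in d = 2 for optimum-reaching (tolerance 0.05
against the exhaustive grid minimum). The full-protein audit runs the
pentapeptide with `L_max_cap = 40`, `dep_cap = 2000`. These are the
package's chosen study sizes; the win margin in d = 4 is typically
20/20, far beyond the sign-test threshold of 15/20 at α = 0.05.

## What the synthetic settings do and do not show

The benchmark landscapes are smooth, separable-plus-weak-coupling
surfaces with known optima; they validate the schedule plumbing, the
law switching and the equilibrium detector, not biological realism.
The simplified force field exercises the full dihedral pipeline
(sampling → geometry → pair terms → annealing) but omits side-chain
atoms, solvation and any calibrated parameterization, so success there
demonstrates correctness and reproducibility of the optimizer, not
predictive folding accuracy.

## Known limitations

* The as-printed quench multiplier makes MQP essentially a single huge
  temperature drop; the complement mode is the practical alternative.
* χ torsions contribute energy only through their cosine terms (no
  side-chain atoms exist to clash).
* The Bose-Einstein law with λ = 0 and clamping is "always accept"
  until ΔE/T reaches ln 2, which keeps BEAP exploratory even at low T;
  λ > 0 sharpens it.
* Variable counts depend on the packaged χ table; chains with
  unconventional residues are rejected rather than guessed.
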