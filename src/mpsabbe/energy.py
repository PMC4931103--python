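"""Energy models: a simplified ECEPP-style backbone force field and
analytic benchmark landscapes for optimizer validation.

The protein energy keeps the ECEPP functional families — 6-12
Lennard-Jones, Coulomb electrostatics, cosine torsion terms and a 12-10
hydrogen bond — over the four backbone atom types (N, CA, C, O), with a
small packaged parameter set.  It is a test harness for the optimizer,
not a reproduction of any published force-field parameterization;
absolute energies are not comparable to ECEPP/2 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .conformation import Conformation, parse_sequence
from .geometry import BackboneGeometryParams, Structure, build_structure

__all__ = [
    "EnergyModel",
    "SimplifiedForceFieldParams",
    "simplified_protein_energy",
    "energy_components",
    "protein_model",
    "benchmark_energy",
    "benchmark_model",
    "MemoizedEnergy",
    "BENCHMARKS",
]

COULOMB_K = 332.0637  # kcal·Å/(mol·e²)
MIN_PAIR_DISTANCE = 0.1  # Å; closer pairs are clamped to keep E finite


@dataclass(frozen=True)
class EnergyModel:
    """Deterministic map from a state (vector or Conformation) to energy."""

    name: str
    evaluate: Callable[[object], float]
    dimension: int

    def __call__(self, state: object) -> float:
        return self.evaluate(state)


@dataclass(frozen=True)
class SimplifiedForceFieldParams:
    """Parameters of the simplified backbone force field.

    Lennard-Jones wells (``lj_epsilon``, kcal/mol) and radii
    (``lj_sigma``, Å) are per atom type, combined by Lorentz-Berthelot
    rules.  Charges are fractional elementary charges per backbone atom
    type.  Torsion terms are (barrier V in kcal/mol, periodicity n,
    phase γ in degrees) per angle class; E = (V/2)(1 + cos(nθ − γ)).
    The 12-10 hydrogen bond acts on nonbonded N···O pairs in place of
    their Lennard-Jones term.
    """

    lj_epsilon: dict[str, float] = field(
        default_factory=lambda: {"N": 0.16, "CA": 0.11, "C": 0.105, "O": 0.21}
    )
    lj_sigma: dict[str, float] = field(
        default_factory=lambda: {"N": 3.25, "CA": 3.40, "C": 3.75, "O": 2.96}
    )
    charges: dict[str, float] = field(
        default_factory=lambda: {"N": -0.35, "CA": 0.10, "C": 0.45, "O": -0.45}
    )
    dielectric: float = 2.0
    torsion: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "phi": (1.0, 3, 0.0),
            "psi": (1.0, 3, 0.0),
            "omega": (10.0, 2, 180.0),
            "chi": (1.4, 3, 0.0),
        }
    )
    hbond_depth: float = 2.0  # kcal/mol
    hbond_r0: float = 2.9  # Å
    cutoff: float = math.inf  # Å; inf = all pairs
    scale_14: float = 0.5  # multiplier on 1-4 LJ/electrostatics; 0 skips

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.lj_epsilon.values()) or self.hbond_depth < 0:
            raise ValueError("well depths must be non-negative")
        if any(s <= 0 for s in self.lj_sigma.values()):
            raise ValueError("sigma must be positive")
        for v, n, _ in self.torsion.values():
            if int(n) not in (1, 2, 3):
                raise ValueError("torsion periodicity must be in {1, 2, 3}")


def _backbone_topology(n_res: int) -> list[tuple[int, int]]:
    """Bonds over atoms ordered N, CA, C, O per residue (4 per residue)."""
    bonds = []
    for i in range(n_res):
        base = 4 * i
        bonds.append((base, base + 1))      # N-CA
        bonds.append((base + 1, base + 2))  # CA-C
        bonds.append((base + 2, base + 3))  # C-O
        if i + 1 < n_res:
            bonds.append((base + 2, base + 4))  # C-N(i+1)
    return bonds


def _bond_separation(n_atoms: int, bonds: list[tuple[int, int]]) -> np.ndarray:
    """Topological bond-count distance between all atom pairs (BFS), capped at 4."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    sep = np.full((n_atoms, n_atoms), 5, dtype=int)
    for s in range(n_atoms):
        sep[s, s] = 0
        frontier = [s]
        for depth in range(1, 5):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if sep[s, v] > depth:
                        sep[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return sep


def energy_components(
    structure: Structure,
    conf: Conformation,
    params: SimplifiedForceFieldParams | None = None,
) -> dict[str, float]:
    """Per-term energies: lj, elec, torsion, hbond (kcal/mol)."""
    p = params or SimplifiedForceFieldParams()
    atoms = structure.atoms
    names = [a.name for a in atoms]
    xyz = np.asarray([a.xyz for a in atoms])
    n = len(atoms)
    sep = _bond_separation(n, _backbone_topology(len(conf.sequence)))

    eps = np.array([p.lj_epsilon[a] for a in names])
    sig = np.array([p.lj_sigma[a] for a in names])
    q = np.array([p.charges[a] for a in names])

    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(r, np.inf)
    r = np.maximum(r, MIN_PAIR_DISTANCE)

    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    sep_ij = sep[iu]
    scale = np.where(sep_ij == 4, p.scale_14, np.where(sep_ij > 4, 1.0, 0.0))
    within = rij <= p.cutoff

    is_n = np.array([nm == "N" for nm in names])
    is_o = np.array([nm == "O" for nm in names])
    hb_pair = (
        (is_n[iu[0]] & is_o[iu[1]]) | (is_o[iu[0]] & is_n[iu[1]])
    ) & (sep_ij > 4)

    eps_ij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    sig_ij = 0.5 * (sig[iu[0]] + sig[iu[1]])
    sr6 = (sig_ij / rij) ** 6
    lj_pair = 4 * eps_ij * (sr6**2 - sr6)
    e_lj = float(np.sum(lj_pair * scale * within * ~hb_pair))

    elec_pair = COULOMB_K * q[iu[0]] * q[iu[1]] / (p.dielectric * rij)
    e_elec = float(np.sum(elec_pair * scale * within))

    ratio = p.hbond_r0 / rij
    hb = p.hbond_depth * (5 * ratio**12 - 6 * ratio**10)
    e_hbond = float(np.sum(hb * hb_pair * within))

    e_torsion = 0.0
    for k, (_, name) in enumerate(conf.angle_names):
        cls = "chi" if name.startswith("chi") else name
        v, per, gamma = p.torsion[cls]
        theta = math.radians(conf.angles[k])
        e_torsion += 0.5 * v * (1 + math.cos(per * theta - math.radians(gamma)))

    return {"lj": e_lj, "elec": e_elec, "torsion": e_torsion, "hbond": e_hbond}


def simplified_protein_energy(
    structure: Structure,
    conf: Conformation,
    params: SimplifiedForceFieldParams | None = None,
) -> float:
    """Total backbone energy: E_LJ + E_elec + E_torsion + E_hbond."""
    c = energy_components(structure, conf, params)
    return c["lj"] + c["elec"] + c["torsion"] + c["hbond"]


def protein_model(
    sequence: str,
    params: SimplifiedForceFieldParams | None = None,
    geometry: BackboneGeometryParams | None = None,
) -> EnergyModel:
    """EnergyModel over Conformations of the given sequence."""
    from .conformation import count_variables

    p = params or SimplifiedForceFieldParams()
    g = geometry or BackboneGeometryParams()

    def evaluate(conf: object) -> float:
        assert isinstance(conf, Conformation)
        return simplified_protein_energy(build_structure(conf, g), conf, p)

    return EnergyModel(
        name=f"simplified_forcefield[{sequence}]",
        evaluate=evaluate,
        dimension=count_variables(parse_sequence(sequence)),
    )


# ---------------------------------------------------------------------------
# analytic benchmark landscapes


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


def _rugged_torsion(x: np.ndarray) -> float:
    """Periodic, multiminimum landscape over angles in degrees.

    Per-coordinate three-well torsion terms plus a weak pairwise cosine
    coupling; the global optimum is obtainable by exhaustive 1-degree
    grid search in small dimension.
    """
    rad = np.radians(x)
    e = float(np.sum(1 + np.cos(3 * rad)))
    n = x.size
    if n > 1:
        di = rad[:, None] - rad[None, :]
        iu = np.triu_indices(n, k=1)
        e += float(np.sum(0.1 * np.cos(di[iu])))
    return e


BENCHMARKS: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": _sphere,
    "rastrigin": _rastrigin,
    "rugged_torsion": _rugged_torsion,
}


def benchmark_energy(name: str, x: Sequence[float] | np.ndarray) -> float:
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; have {sorted(BENCHMARKS)}")
    return BENCHMARKS[name](np.asarray(x, dtype=float))


def benchmark_model(name: str, dimension: int) -> EnergyModel:
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; have {sorted(BENCHMARKS)}")
    fn = BENCHMARKS[name]
    return EnergyModel(
        name=name,
        evaluate=lambda x: fn(np.asarray(x, dtype=float)),
        dimension=dimension,
    )


class MemoizedEnergy:
    """Per-run energy cache keyed by the state's byte image.

    The annealing phases re-evaluate the current solution's energy; the
    cache makes that reuse free while keeping EnergyModel pure.
    """

    def __init__(self, model: EnergyModel, maxsize: int = 4096):
        self.model = model
        self.maxsize = maxsize
        self._cache: dict[bytes, float] = {}
        self.hits = 0
        self.misses = 0

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def dimension(self) -> int:
        return self.model.dimension

    def __call__(self, state: object) -> float:
        vec = state.angles if isinstance(state, Conformation) else np.asarray(state)
        key = np.ascontiguousarray(vec).tobytes()
        if key in self._cache:
            self.hits += 1
            return self._cache[key]
        self.misses += 1
        value = self.model.evaluate(state)
        if len(self._cache) >= self.maxsize:
            self._cache.clear()
        self._cache[key] = value
        return value
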