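"""Protein conformations as vectors of discrete dihedral angles.

The optimizer's state for the protein folding problem is the full set of
backbone and side-chain torsions: per residue one phi, one psi, one omega
and ``n_chi`` chi angles, all in degrees on [0, 360).  Omega is held rigid
at 180 degrees (trans peptide bond); phi and psi are restricted to the
allowed regions of the Ramachandran plot, and chi angles are free.
Angles are discretized on a uniform grid (default 1 degree per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Residue",
    "AngleRanges",
    "Conformation",
    "CHI_COUNTS",
    "parse_sequence",
    "random_conformation",
    "perturb",
    "count_variables",
]

#: Number of side-chain chi torsions per residue type (standard rotamer
#: conventions: none for Gly/Ala, up to four for Arg/Lys).
CHI_COUNTS: dict[str, int] = {
    "G": 0, "A": 0,
    "S": 1, "C": 1, "T": 1, "V": 1, "P": 1,
    "D": 2, "N": 2, "L": 2, "I": 2, "F": 2, "Y": 2, "W": 2, "H": 2,
    "E": 3, "Q": 3, "M": 3,
    "K": 4, "R": 4,
}

OMEGA_DEGREES = 180.0


@dataclass(frozen=True)
class Residue:
    """One amino acid: single-letter code plus its chi-torsion count."""

    code: str
    n_chi: int

    def __post_init__(self) -> None:
        if self.code not in CHI_COUNTS:
            raise ValueError(f"unknown residue code {self.code!r}")
        if not 0 <= self.n_chi <= 4:
            raise ValueError(f"n_chi must be in [0, 4], got {self.n_chi}")

    @property
    def n_variables(self) -> int:
        # phi + psi + omega + chi angles
        return 3 + self.n_chi


def parse_sequence(sequence: str | Sequence[Residue]) -> tuple[Residue, ...]:
    """Turn a one-letter string into Residue records (passes Residues through)."""
    if isinstance(sequence, str):
        residues = []
        for i, code in enumerate(sequence.upper()):
            if code not in CHI_COUNTS:
                raise ValueError(
                    f"unknown residue code {code!r} at position {i + 1}"
                )
            residues.append(Residue(code, CHI_COUNTS[code]))
        return tuple(residues)
    return tuple(sequence)


def _as_interval_array(intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(intervals, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be a sequence of (lo, hi) pairs")
    if np.any(arr[:, 0] > arr[:, 1]) or arr.min() < 0 or arr.max() > 360:
        raise ValueError("intervals must be non-empty and within [0, 360]")
    return arr


@dataclass(frozen=True)
class AngleRanges:
    """Allowed closed degree intervals per torsion class.

    The defaults encode the Ramachandran-derived backbone windows: phi on
    [180, 300] ∪ [45, 60]; psi on [20, 205] ∪ [300, 330] (the union of the
    overlapping [20, 180] and [180, 205] windows with [300, 330]); omega
    pinned at 180; chi unrestricted on [0, 360).
    """

    phi_ranges: tuple[tuple[float, float], ...] = ((180.0, 300.0), (45.0, 60.0))
    psi_ranges: tuple[tuple[float, float], ...] = ((20.0, 205.0), (300.0, 330.0))
    chi_ranges: tuple[tuple[float, float], ...] = ((0.0, 359.0),)
    omega_value: float = OMEGA_DEGREES
    step_granularity: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.phi_ranges, self.psi_ranges, self.chi_ranges):
            _as_interval_array(r)
        if self.step_granularity <= 0:
            raise ValueError("step_granularity must be positive")

    def intervals_for(self, kind: str) -> tuple[tuple[float, float], ...]:
        if kind == "phi":
            return self.phi_ranges
        if kind == "psi":
            return self.psi_ranges
        if kind.startswith("chi"):
            return self.chi_ranges
        raise ValueError(f"no sampled intervals for angle class {kind!r}")

    def contains(self, kind: str, value: float) -> bool:
        if kind == "omega":
            return value == self.omega_value
        return any(lo <= value <= hi for lo, hi in self.intervals_for(kind))

    def sample(self, kind: str, rng: np.random.Generator) -> float:
        """Draw one discretized angle uniformly over the class intervals."""
        intervals = _as_interval_array(self.intervals_for(kind))
        step = self.step_granularity
        # uniform over the discrete grid points of every interval
        counts = np.floor((intervals[:, 1] - intervals[:, 0]) / step).astype(int) + 1
        total = counts.sum()
        idx = int(rng.integers(total))
        seg = int(np.searchsorted(np.cumsum(counts), idx, side="right"))
        offset = idx - (np.cumsum(counts)[seg] - counts[seg])
        return float(intervals[seg, 0] + offset * step) % 360.0


def _angle_names(residues: tuple[Residue, ...]) -> tuple[tuple[int, str], ...]:
    names: list[tuple[int, str]] = []
    for i, res in enumerate(residues):
        names.append((i, "phi"))
        names.append((i, "psi"))
        names.append((i, "omega"))
        for c in range(res.n_chi):
            names.append((i, f"chi{c + 1}"))
    return tuple(names)


@dataclass(frozen=True)
class Conformation:
    """Immutable dihedral-angle state of a peptide chain.

    ``angles`` stacks, residue by residue, phi, psi, omega, then the chi
    torsions, matching :func:`count_variables`.
    """

    sequence: tuple[Residue, ...]
    angles: np.ndarray
    seed: int | None = None
    _names: tuple[tuple[int, str], ...] = field(
        default=(), compare=False, repr=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", tuple(self.sequence))
        angles = np.asarray(self.angles, dtype=float)
        angles.setflags(write=False)
        object.__setattr__(self, "angles", angles)
        names = _angle_names(self.sequence)
        object.__setattr__(self, "_names", names)
        if angles.shape != (len(names),):
            raise ValueError(
                f"angle vector length {angles.shape} does not match the "
                f"{len(names)} variables of the sequence"
            )

    @property
    def angle_names(self) -> tuple[tuple[int, str], ...]:
        """(residue_index, angle_name) label for each vector entry."""
        return self._names

    def angle(self, residue_index: int, name: str) -> float:
        for k, (i, n) in enumerate(self._names):
            if i == residue_index and n == name:
                return float(self.angles[k])
        raise KeyError((residue_index, name))

    def validate(self, ranges: AngleRanges) -> None:
        for k, (i, name) in enumerate(self._names):
            v = float(self.angles[k])
            if not 0 <= v < 360:
                raise ValueError(f"angle {name}[{i}] = {v} outside [0, 360)")
            if not ranges.contains(name, v):
                raise ValueError(f"angle {name}[{i}] = {v} violates its range")

    def replace_angles(self, angles: np.ndarray) -> "Conformation":
        return Conformation(self.sequence, angles, self.seed)


def count_variables(sequence: str | Sequence[Residue]) -> int:
    """Total dihedral variable count: per residue phi+psi+omega+n_chi.

    Terminal residues contribute their full phi/psi/omega triple even
    though residue 1's phi and residue n's psi have no geometric effect;
    the uniform rule keeps the count reproducible.
    """
    return sum(r.n_variables for r in parse_sequence(sequence))


def random_conformation(
    sequence: str | Sequence[Residue],
    ranges: AngleRanges | None = None,
    seed: int | np.random.Generator = 0,
) -> Conformation:
    """Sample a conformation uniformly within the allowed angle intervals.

    Deterministic in (sequence, ranges, seed): the same seed always yields
    the identical angle vector.
    """
    residues = parse_sequence(sequence)
    if not residues:
        raise ValueError("sequence must be non-empty")
    ranges = ranges or AngleRanges()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values = []
    for _, name in _angle_names(residues):
        if name == "omega":
            values.append(ranges.omega_value)
        else:
            values.append(ranges.sample(name, rng))
    conf = Conformation(
        residues,
        np.array(values),
        seed if isinstance(seed, int) else None,
    )
    return conf


def perturb(
    conf: Conformation,
    ranges: AngleRanges | None = None,
    move_width: float = 360.0,
    n_moves: int = 1,
    rng: np.random.Generator | int = 0,
) -> Conformation:
    """Resample up to ``n_moves`` non-omega angles; returns a new Conformation.

    The proposal redraws each chosen angle uniformly within a window of
    ``move_width`` degrees around its current value, clipped to the allowed
    intervals of its class (out-of-range proposals are resampled on the
    grid restricted to the window).  ``move_width >= 360`` degenerates to a
    uniform redraw over the whole class range — the default move kernel.
    The input conformation is never modified.
    """
    if n_moves < 1:
        raise ValueError("n_moves must be >= 1")
    if move_width <= 0:
        raise ValueError("move_width must be positive")
    ranges = ranges or AngleRanges()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    names = conf.angle_names
    movable = [k for k, (_, n) in enumerate(names) if n != "omega"]
    angles = np.array(conf.angles)
    chosen = rng.choice(len(movable), size=min(n_moves, len(movable)), replace=False)
    for c in chosen:
        k = movable[int(c)]
        name = names[k][1]
        if move_width >= 360.0:
            angles[k] = ranges.sample(name, rng)
        else:
            current = angles[k]
            for _ in range(1000):  # rejection-sample within the window
                delta = rng.uniform(-move_width / 2, move_width / 2)
                step = ranges.step_granularity
                proposal = (current + round(delta / step) * step) % 360.0
                if ranges.contains(name, proposal):
                    angles[k] = proposal
                    break
            else:
                angles[k] = ranges.sample(name, rng)
    return conf.replace_angles(angles)
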