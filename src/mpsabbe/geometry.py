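"""Backbone Cartesian geometry: building coordinates from dihedrals,
measuring torsions back, PDB output, and superposition RMSD.

Coordinates are built by sequential natural extension: each atom is placed
from the previous three using a bond length, a bond angle and a torsion,
which makes the construction exactly invertible — the torsion measured
from the built coordinates reproduces the input dihedral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .conformation import Conformation

__all__ = [
    "BackboneGeometryParams",
    "Atom",
    "Structure",
    "build_structure",
    "measure_torsion",
    "measured_backbone_torsions",
    "rmsd",
    "write_pdb",
    "read_pdb_backbone",
]


@dataclass(frozen=True)
class BackboneGeometryParams:
    """Idealized peptide bond lengths (Å) and angles (degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    c_o: float = 1.231

    def __post_init__(self) -> None:
        for length in (self.n_ca, self.ca_c, self.c_n):
            if not 1.0 < length < 2.0:
                raise ValueError(f"bond length {length} outside (1, 2) Å")
        for ang in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca):
            if not 90 < ang < 150:
                raise ValueError(f"bond angle {ang} outside (90, 150) degrees")


@dataclass(frozen=True)
class Atom:
    residue_index: int  # 1-based
    name: str  # N, CA, C, O
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Structure:
    atoms: tuple[Atom, ...]
    residue_codes: tuple[str, ...] = ()

    def coords(self, atom_selection: Iterable[str] | None = None) -> np.ndarray:
        sel = set(atom_selection) if atom_selection is not None else None
        pts = [a.xyz for a in self.atoms if sel is None or a.name in sel]
        return np.asarray(pts, dtype=float)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension placement of atom D from chain A-B-C."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(tor),
            -length * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_torsion(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Dihedral of the four points, degrees in [0, 360)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x)) % 360.0


def build_structure(
    conf: Conformation, params: BackboneGeometryParams | None = None
) -> Structure:
    """Backbone N/CA/C/O coordinates from the dihedral vector.

    Torsion roles along the chain: psi(i) places N(i+1), omega(i+1) places
    CA(i+1), phi(i+1) places C(i+1).  Residue 1's phi and omega and the
    last residue's psi do not enter the construction (no preceding or
    following atoms); they remain pure bookkeeping variables.
    """
    p = params or BackboneGeometryParams()
    n_res = len(conf.sequence)

    def ang(i: int, name: str) -> float:
        return conf.angle(i, name)

    # first residue frame: N at origin, CA on +x, C in the xy-plane
    N0 = np.zeros(3)
    CA0 = np.array([p.n_ca, 0.0, 0.0])
    theta = math.radians(p.ang_n_ca_c)
    C0 = CA0 + p.ca_c * np.array([-math.cos(theta), math.sin(theta), 0.0])

    n_xyz = [N0]
    ca_xyz = [CA0]
    c_xyz = [C0]
    for i in range(1, n_res):
        Ni = _place_atom(
            n_xyz[-1], ca_xyz[-1], c_xyz[-1], p.c_n, p.ang_ca_c_n, ang(i - 1, "psi")
        )
        CAi = _place_atom(
            ca_xyz[-1], c_xyz[-1], Ni, p.n_ca, p.ang_c_n_ca, ang(i, "omega")
        )
        Ci = _place_atom(
            c_xyz[-1], Ni, CAi, p.ca_c, p.ang_n_ca_c, ang(i, "phi")
        )
        n_xyz.append(Ni)
        ca_xyz.append(CAi)
        c_xyz.append(Ci)

    atoms: list[Atom] = []
    for i in range(n_res):
        atoms.append(Atom(i + 1, "N", tuple(n_xyz[i])))
        atoms.append(Atom(i + 1, "CA", tuple(ca_xyz[i])))
        atoms.append(Atom(i + 1, "C", tuple(c_xyz[i])))
        # carbonyl O: in the C(i) plane, opposite N(i+1); terminal O along
        # the N-CA..C bisector continuation (cosmetic, for PDB output)
        if i + 1 < n_res:
            # O anti to N(i+1) in the sp2 plane of C(i)
            u = c_xyz[i] - ca_xyz[i]
            v = n_xyz[i + 1] - c_xyz[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            direction = u - v
            direction /= np.linalg.norm(direction)
            o = c_xyz[i] + p.c_o * direction
        else:
            u = c_xyz[i] - ca_xyz[i]
            u /= np.linalg.norm(u)
            o = c_xyz[i] + p.c_o * u
        atoms.append(Atom(i + 1, "O", tuple(o)))
    return Structure(tuple(atoms), tuple(r.code for r in conf.sequence))


def measured_backbone_torsions(struct: Structure) -> dict[tuple[int, str], float]:
    """phi/psi/omega measured from coordinates, keyed by (residue, name).

    Only geometrically defined torsions appear: phi from residue 2 on,
    psi up to residue n−1, omega from residue 2 on.
    """
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a in struct.atoms:
        by_res.setdefault(a.residue_index, {})[a.name] = np.asarray(a.xyz)
    n = max(by_res)
    out: dict[tuple[int, str], float] = {}
    for i in range(1, n + 1):
        r = by_res[i]
        if i > 1:
            prev = by_res[i - 1]
            out[(i, "phi")] = measure_torsion(prev["C"], r["N"], r["CA"], r["C"])
            out[(i, "omega")] = measure_torsion(
                prev["CA"], prev["C"], r["N"], r["CA"]
            )
        if i < n:
            nxt = by_res[i + 1]
            out[(i, "psi")] = measure_torsion(r["N"], r["CA"], r["C"], nxt["N"])
    return out


def rmsd(
    a: Structure | np.ndarray,
    b: Structure | np.ndarray,
    atom_selection: Iterable[str] | None = ("CA",),
) -> float:
    """Minimum RMSD over rigid rotations+translations (Kabsch superposition).

    Defaults to CA atoms.  Symmetric in its arguments.
    """
    pa = a.coords(atom_selection) if isinstance(a, Structure) else np.asarray(a, float)
    pb = b.coords(atom_selection) if isinstance(b, Structure) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError(f"atom count mismatch: {pa.shape[0]} vs {pb.shape[0]}")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    # recompute the residual from the rotated coordinates: the rssd
    # reported by align_vectors loses precision for near-congruent sets
    resid = pa - rot.apply(pb)
    return float(math.sqrt(np.mean(np.sum(resid**2, axis=1))))


_PDB_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb(struct: Structure, path: str) -> None:
    """Standard ATOM records, chain A, occupancy 1.00, B-factor 0.00."""
    lines = []
    for serial, atom in enumerate(struct.atoms, start=1):
        code = (
            struct.residue_codes[atom.residue_index - 1]
            if struct.residue_codes
            else "G"
        )
        resname = _THREE.get(code, "UNK")
        x, y, z = atom.xyz
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} A"
            f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {_PDB_ELEMENT[atom.name]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb_backbone(path: str) -> Structure:
    """Read ATOM records keeping backbone atoms (N, CA, C, O) only."""
    atoms: list[Atom] = []
    codes: dict[int, str] = {}
    rev = {v: k for k, v in _THREE.items()}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            name = line[12:16].strip()
            if name not in ("N", "CA", "C", "O"):
                continue
            res_idx = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            atoms.append(Atom(res_idx, name, xyz))
            codes[res_idx] = rev.get(line[17:20].strip(), "G")
    residue_codes = tuple(codes[i] for i in sorted(codes))
    return Structure(tuple(atoms), residue_codes)
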