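"""Structure input and covalent-topology assignment.

Reads single- and multi-frame XYZ and PDB files containing water and,
optionally, DMSO, glycerol or methane, assigns covalent bonds from
interatomic distances, groups atoms into molecules and types each
molecule by its molecular formula.  All coordinates are in Angstrom.

Internally every index is 0-based; indices in error messages and
reports are 1-based, following the usual convention of chemistry file
formats.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MoleculeKind",
    "AtomRecord",
    "MoleculeUnit",
    "MolecularSystem",
    "ParseError",
    "AmbiguousHydrogenError",
    "assign_molecules",
    "read_xyz",
    "read_pdb",
    "write_xyz",
]

#: Elements the parsers accept.  More than enough for aqueous systems;
#: unknown symbols are treated as input errors rather than silently kept.
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Br I Fe Zn Cu Mn".split()
)

#: Covalent cutoffs (Angstrom) per unordered element pair.  Generous
#: enough for stretched O-H bonds (0.968 A in hydrogen-bonded water)
#: while staying far below the shortest hydrogen bond considered (1.7 A).
COVALENT_CUTOFFS: dict[frozenset[str], float] = {
    frozenset(("O", "H")): 1.2,
    frozenset(("C", "H")): 1.3,
    frozenset(("S", "O")): 1.7,
    frozenset(("C", "C")): 1.7,
    frozenset(("C", "O")): 1.7,
    frozenset(("C", "S")): 2.0,  # S-C in DMSO is ~1.8 A
}

_MAX_COVALENT = max(COVALENT_CUTOFFS.values())


class MoleculeKind(str, enum.Enum):
    """Molecule types the shift model distinguishes."""

    WATER = "water"
    DMSO = "dmso"
    GLYCEROL = "glycerol"
    METHANE = "methane"
    OTHER = "other"


#: molecular formula (sorted element counts) -> kind
_FORMULA_KINDS = {
    (("H", 2), ("O", 1)): MoleculeKind.WATER,
    (("C", 2), ("H", 6), ("O", 1), ("S", 1)): MoleculeKind.DMSO,
    (("C", 3), ("H", 8), ("O", 3)): MoleculeKind.GLYCEROL,
    (("C", 1), ("H", 4)): MoleculeKind.METHANE,
}

#: PDB residue-name hints, reconciled against formula-based typing.
_RESNAME_HINTS = {
    "HOH": MoleculeKind.WATER,
    "WAT": MoleculeKind.WATER,
    "SOL": MoleculeKind.WATER,
    "DMS": MoleculeKind.DMSO,
    "GOL": MoleculeKind.GLYCEROL,
}


class ParseError(ValueError):
    """Raised for malformed structure files; message carries the line number."""


class AmbiguousHydrogenError(ValueError):
    """Raised when an H atom lies within covalent range of two heavy atoms."""


@dataclass
class AtomRecord:
    """One atom: element symbol, Cartesian position (A) and molecule id."""

    index: int
    element: str
    position: np.ndarray
    molecule_id: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index + 1}: position must be a finite 3-vector")
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.index + 1}: unknown element symbol {self.element!r}")


@dataclass
class MoleculeUnit:
    """A connected covalent component with a chemical type and role atoms.

    ``role_atoms`` maps labels such as ``water_O``, ``water_H1``,
    ``dmso_O``, ``hydroxyl_O1`` or ``methyl_H3`` to atom indices so that
    downstream code never needs to re-derive which oxygen is the S=O
    acceptor or which hydrogens belong to methyl groups.
    """

    kind: MoleculeKind
    atom_indices: list[int]
    role_atoms: dict[str, int] = field(default_factory=dict)


@dataclass
class MolecularSystem:
    """Atoms, covalent bonds and typed molecules for one frame."""

    atoms: list[AtomRecord]
    covalent_bonds: list[tuple[int, int]]
    molecules: list[MoleculeUnit]
    frame_id: int = 0

    # -- geometric helpers -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.atoms[i].position - self.atoms[j].position))

    def angle(self, i: int, j: int, k: int) -> float:
        """Angle i-j-k at vertex j, in degrees."""
        u = self.atoms[i].position - self.atoms[j].position
        v = self.atoms[k].position - self.atoms[j].position
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def covalent_neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.covalent_bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def water_oh_lengths(self, mol_id: int) -> tuple[float, float]:
        """The two covalent O-H bond lengths of a water molecule."""
        mol = self.molecules[mol_id]
        if mol.kind is not MoleculeKind.WATER:
            raise ValueError(f"molecule {mol_id + 1} is not water")
        o = mol.role_atoms["water_O"]
        h1 = mol.role_atoms["water_H1"]
        h2 = mol.role_atoms["water_H2"]
        return self.distance(o, h1), self.distance(o, h2)

    def copy_with_positions(self, positions: np.ndarray, frame_id: int | None = None) -> "MolecularSystem":
        """Same topology with new coordinates (used for trajectory frames)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError("positions shape mismatch")
        atoms = [
            AtomRecord(a.index, a.element, positions[i].copy(), a.molecule_id)
            for i, a in enumerate(self.atoms)
        ]
        return MolecularSystem(
            atoms=atoms,
            covalent_bonds=list(self.covalent_bonds),
            molecules=[
                MoleculeUnit(m.kind, list(m.atom_indices), dict(m.role_atoms))
                for m in self.molecules
            ],
            frame_id=self.frame_id if frame_id is None else frame_id,
        )


def _pair_cutoff(el1: str, el2: str) -> float | None:
    return COVALENT_CUTOFFS.get(frozenset((el1, el2)))


def _molecule_kind(elements: Iterable[str]) -> MoleculeKind:
    key = tuple(sorted(Counter(elements).items()))
    return _FORMULA_KINDS.get(key, MoleculeKind.OTHER)


def _fill_roles(kind: MoleculeKind, indices: list[int], atoms: list[AtomRecord],
                adjacency: dict[int, list[int]]) -> dict[str, int]:
    els = {i: atoms[i].element for i in indices}
    roles: dict[str, int] = {}
    if kind is MoleculeKind.WATER:
        o = next(i for i in indices if els[i] == "O")
        h1, h2 = sorted(i for i in indices if els[i] == "H")
        roles = {"water_O": o, "water_H1": h1, "water_H2": h2}
    elif kind is MoleculeKind.METHANE:
        c = next(i for i in indices if els[i] == "C")
        roles["methane_C"] = c
        for n, h in enumerate(sorted(i for i in indices if els[i] == "H"), 1):
            roles[f"ch_H{n}"] = h
    elif kind is MoleculeKind.DMSO:
        s = next(i for i in indices if els[i] == "S")
        o = next(i for i in indices if els[i] == "O" and s in adjacency[i])
        roles = {"dmso_S": s, "dmso_O": o}
        for n, c in enumerate(sorted(i for i in indices if els[i] == "C"), 1):
            roles[f"dmso_C{n}"] = c
        for n, h in enumerate(sorted(i for i in indices if els[i] == "H"), 1):
            roles[f"methyl_H{n}"] = h
    elif kind is MoleculeKind.GLYCEROL:
        oxygens = sorted(i for i in indices if els[i] == "O")
        n_oh = 0
        ch_n = 0
        for n, o in enumerate(oxygens, 1):
            roles[f"hydroxyl_O{n}"] = o
        for i in sorted(indices):
            if els[i] != "H":
                continue
            heavy = adjacency[i][0]
            if els[heavy] == "O":
                n_oh += 1
                roles[f"hydroxyl_H{oxygens.index(heavy) + 1}"] = i
            else:
                ch_n += 1
                roles[f"ch_H{ch_n}"] = i
        for n, c in enumerate(sorted(i for i in indices if els[i] == "C"), 1):
            roles[f"backbone_C{n}"] = c
    return roles


def assign_molecules(atoms: Sequence[AtomRecord], frame_id: int = 0) -> MolecularSystem:
    """Assign covalent bonds, group connected components, type molecules.

    Bonds come from element-pair distance cutoffs (:data:`COVALENT_CUTOFFS`).
    Each hydrogen must fall within covalent range of at most one heavy
    atom; two candidates raise :class:`AmbiguousHydrogenError`, zero
    candidates leave the H flagged as its own ``other`` component with a
    warning.  Components with an unrecognized formula are typed ``other``
    (warning, not an error).
    """
    atoms = [AtomRecord(i, a.element, a.position) for i, a in enumerate(atoms)]
    n = len(atoms)
    bonds: list[tuple[int, int]] = []
    if n > 1:
        tree = cKDTree(np.array([a.position for a in atoms]))
        candidate_pairs = sorted(tree.query_pairs(_MAX_COVALENT))
        h_heavy: dict[int, list[int]] = {i: [] for i in range(n) if atoms[i].element == "H"}
        for i, j in candidate_pairs:
            cut = _pair_cutoff(atoms[i].element, atoms[j].element)
            if cut is None or np.linalg.norm(atoms[i].position - atoms[j].position) >= cut:
                continue
            if atoms[i].element == "H":
                h_heavy[i].append(j)
            elif atoms[j].element == "H":
                h_heavy[j].append(i)
            else:
                bonds.append((i, j))
        for h, heavies in h_heavy.items():
            if len(heavies) > 1:
                cands = ", ".join(
                    f"{atoms[k].element}{k + 1}" for k in heavies
                )
                raise AmbiguousHydrogenError(
                    f"H{h + 1} lies within covalent range of several heavy atoms: {cands}"
                )
            if len(heavies) == 1:
                bonds.append(tuple(sorted((h, heavies[0]))))
            else:
                warnings.warn(f"H{h + 1} has no covalent partner; left unassigned")
        bonds.sort()

    # connected components via union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    molecules: list[MoleculeUnit] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        indices = sorted(groups[root])
        kind = _molecule_kind(atoms[i].element for i in indices)
        if kind is MoleculeKind.OTHER and len(indices) > 1:
            formula = "".join(
                f"{el}{cnt}" for el, cnt in sorted(Counter(atoms[i].element for i in indices).items())
            )
            warnings.warn(f"unrecognized molecular formula {formula}; typed 'other'")
        mol_id = len(molecules)
        for i in indices:
            atoms[i].molecule_id = mol_id
        molecules.append(
            MoleculeUnit(kind, indices, _fill_roles(kind, indices, atoms, adjacency))
        )
    return MolecularSystem(atoms=atoms, covalent_bonds=bonds, molecules=molecules, frame_id=frame_id)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> list[MolecularSystem]:
    """Read a (possibly multi-frame) XYZ file.

    Frames are concatenated blocks of: atom-count line, comment line and
    ``element x y z`` records.  Atoms keep file order; positions are in
    Angstrom; ``frame_id`` runs sequentially from 0.  Malformed count
    lines, non-numeric coordinates and truncated frames raise
    :class:`ParseError` naming the offending line.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularSystem] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():  # tolerate trailing blank lines
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"line {ln + 1}: expected an atom count, got {lines[ln]!r}")
        if natoms <= 0:
            raise ParseError(f"line {ln + 1}: atom count must be positive")
        if ln + 2 + natoms > len(lines):
            raise ParseError(
                f"line {ln + 1}: frame declares {natoms} atoms but the file is truncated"
            )
        atoms = []
        for k in range(natoms):
            lno = ln + 2 + k
            parts = lines[lno].split()
            if len(parts) < 4:
                raise ParseError(f"line {lno + 1}: expected 'element x y z'")
            el = parts[0].capitalize()
            if el not in KNOWN_ELEMENTS:
                raise ParseError(f"line {lno + 1}: unknown element {parts[0]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {lno + 1}: non-numeric coordinate")
            atoms.append(AtomRecord(k, el, np.array(xyz)))
        frames.append(assign_molecules(atoms, frame_id=len(frames)))
        ln += 2 + natoms
    if not frames:
        raise ParseError("line 1: empty XYZ file")
    return frames


def write_xyz(systems: MolecularSystem | Sequence[MolecularSystem], path: str | Path,
              comment: str = "") -> None:
    """Write one or several frames as concatenated XYZ blocks (6 decimals)."""
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    with open(path, "w") as fh:
        for sys_ in systems:
            fh.write(f"{sys_.n_atoms}\n{comment or f'frame {sys_.frame_id}'}\n")
            for a in sys_.atoms:
                x, y, z = a.position
                fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> list[MolecularSystem]:
    """Read ATOM/HETATM records of a PDB file (one system per MODEL).

    Residue names HOH/WAT/SOL, DMS and GOL are treated as hints only;
    the formula-derived type always wins, with a warning if the two
    disagree.  Records without an interpretable element raise
    :class:`ParseError`.  Multi-model files must have identical atom
    counts per model.
    """
    st = gemmi.read_pdb(str(path))
    frames: list[MolecularSystem] = []
    for model in st:
        atoms: list[AtomRecord] = []
        hints: list[tuple[str, MoleculeKind]] = []
        for chain in model:
            for res in chain:
                hint = _RESNAME_HINTS.get(res.name.strip().upper())
                for atom in res:
                    el = atom.element.name
                    if not el or el == "X":
                        raise ParseError(
                            f"atom {atom.name!r} in residue {res.name!r}: "
                            "missing element field and unrecognizable atom name"
                        )
                    idx = len(atoms)
                    atoms.append(AtomRecord(idx, el, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
                    if hint is not None:
                        hints.append((f"{res.name}:{idx}", hint))
        system = assign_molecules(atoms, frame_id=len(frames))
        for label, hinted in hints:
            idx = int(label.split(":")[1])
            mol = system.molecules[system.atoms[idx].molecule_id]
            if mol.kind is not hinted:
                warnings.warn(
                    f"residue name suggests {hinted.value} but formula typing gives "
                    f"{mol.kind.value} for atom {idx + 1}; formula typing wins"
                )
        frames.append(system)
    if not frames:
        raise ParseError("PDB file contains no atoms")
    counts = {f.n_atoms for f in frames}
    if len(counts) > 1:
        raise ParseError(f"MODEL frames have differing atom counts: {sorted(counts)}")
    return frames
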