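"""Hydrogen-bond detection and per-water bonding profiles.

A conventional hydrogen bond is an O-H group pointing at an acceptor
oxygen with an H...O distance below 2.5 A and (optionally) a donor-H-
acceptor angle above 150 deg -- the classic Luzar-Chandler style
geometric criterion that restricts the count to the first solvation
shell.  CH...O contacts (methyl or methine hydrogens near a water
oxygen) are collected separately with a distance-only criterion.

Acceptor oxygens may belong to water, to DMSO (the S=O oxygen) or to
glycerol (hydroxyl oxygens).  Donor O-H groups come from water and
glycerol; C-H donors from DMSO, glycerol and methane.  Shift
predictions are only made for water oxygens, but glycerol/DMSO
partners influence the water profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from scipy.spatial import cKDTree
import numpy as np

from .geometry_io import MolecularSystem, MoleculeKind

__all__ = [
    "HydrogenBond",
    "WaterHBondProfile",
    "detect_hbonds",
    "detect_ch_contacts",
    "profile_waters",
]

R_MAX_CONVENTIONAL = 2.5   # A, first-shell H...O cutoff
ANGLE_MIN = 150.0          # deg, donor-H...acceptor
R_MAX_CH = 3.0             # A, CH...O contact cutoff (no angle criterion)


@dataclass(frozen=True)
class HydrogenBond:
    """One detected donor-H...acceptor interaction.

    ``conventional`` is True for O-H donors and False for C-H contacts.
    ``r_hb`` is the H...acceptor distance -- the model's sole geometric
    input per bond -- and ``angle_dha`` the donor-H...acceptor angle.
    """

    donor_heavy: int
    hydrogen: int
    acceptor_heavy: int
    r_hb: float
    angle_dha: float
    donor_kind: MoleculeKind
    acceptor_kind: MoleculeKind
    donor_mol: int
    acceptor_mol: int
    conventional: bool = True


@dataclass
class WaterHBondProfile:
    """Bonding environment of one water molecule.

    ``dangling`` is True when the water donates fewer than two
    conventional bonds, i.e. it has at least one free O-H; donations to
    DMSO or glycerol acceptors count toward ``n_donated``.
    """

    water: int
    accepted: list[HydrogenBond] = field(default_factory=list)
    donated: list[HydrogenBond] = field(default_factory=list)
    ch_contacts: list[HydrogenBond] = field(default_factory=list)
    oh_lengths: tuple[float, float] = (0.0, 0.0)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def n_donated(self) -> int:
        return len(self.donated)

    @property
    def dangling(self) -> bool:
        return self.n_donated < 2


def _oh_donors(system: MolecularSystem) -> list[tuple[int, int, int]]:
    """(O index, H index, molecule id) for every covalent O-H group."""
    donors = []
    for i, j in system.covalent_bonds:
        if {system.atoms[i].element, system.atoms[j].element} != {"O", "H"}:
            continue
        o, h = (i, j) if system.atoms[i].element == "O" else (j, i)
        mol = system.atoms[o].molecule_id
        if system.molecules[mol].kind in (MoleculeKind.WATER, MoleculeKind.GLYCEROL):
            donors.append((o, h, mol))
    return donors


def _ch_donors(system: MolecularSystem) -> list[tuple[int, int, int]]:
    donors = []
    for i, j in system.covalent_bonds:
        if {system.atoms[i].element, system.atoms[j].element} != {"C", "H"}:
            continue
        c, h = (i, j) if system.atoms[i].element == "C" else (j, i)
        mol = system.atoms[c].molecule_id
        if system.molecules[mol].kind in (
            MoleculeKind.DMSO, MoleculeKind.GLYCEROL, MoleculeKind.METHANE,
        ):
            donors.append((c, h, mol))
    return donors


def _acceptor_oxygens(system: MolecularSystem, water_only: bool = False) -> list[tuple[int, int]]:
    """(O index, molecule id) of oxygens that can accept a hydrogen bond."""
    acceptors = []
    for mid, mol in enumerate(system.molecules):
        if mol.kind is MoleculeKind.WATER:
            acceptors.append((mol.role_atoms["water_O"], mid))
        elif water_only:
            continue
        elif mol.kind is MoleculeKind.DMSO:
            acceptors.append((mol.role_atoms["dmso_O"], mid))
        elif mol.kind is MoleculeKind.GLYCEROL:
            for label, idx in mol.role_atoms.items():
                if label.startswith("hydroxyl_O"):
                    acceptors.append((idx, mid))
    return acceptors


def _detect(system: MolecularSystem, donors, acceptors, r_max: float,
            angle_min: float | None, conventional: bool) -> list[HydrogenBond]:
    if not donors or not acceptors:
        return []
    acc_idx = np.array([a for a, _ in acceptors])
    acc_mol = {a: m for a, m in acceptors}
    tree = cKDTree(system.positions[acc_idx])
    bonds: list[HydrogenBond] = []
    for heavy, h, dmol in donors:
        for k in tree.query_ball_point(system.atoms[h].position, r_max):
            a = int(acc_idx[k])
            amol = acc_mol[a]
            if amol == dmol:
                continue
            r = system.distance(h, a)
            if r >= r_max:
                continue
            ang = system.angle(heavy, h, a)
            if angle_min is not None and ang <= angle_min:
                continue
            bonds.append(HydrogenBond(
                donor_heavy=heavy, hydrogen=h, acceptor_heavy=a,
                r_hb=r, angle_dha=ang,
                donor_kind=system.molecules[dmol].kind,
                acceptor_kind=system.molecules[amol].kind,
                donor_mol=dmol, acceptor_mol=amol,
                conventional=conventional,
            ))
    bonds.sort(key=lambda b: (b.hydrogen, b.acceptor_heavy))
    return bonds


def detect_hbonds(system: MolecularSystem, r_max: float = R_MAX_CONVENTIONAL,
                  angle_min: float = ANGLE_MIN, use_angle: bool = True) -> list[HydrogenBond]:
    """Detect conventional (O-H donor) hydrogen bonds.

    Emits a bond for every intermolecular (O-H, acceptor O) pair with
    H...O distance below ``r_max`` and, when ``use_angle`` is set,
    donor-H...acceptor angle above ``angle_min``.  An empty list is a
    valid result.
    """
    return _detect(system, _oh_donors(system), _acceptor_oxygens(system),
                   r_max, angle_min if use_angle else None, conventional=True)


def detect_ch_contacts(system: MolecularSystem, r_max: float = R_MAX_CH) -> list[HydrogenBond]:
    """Detect CH...O contacts onto water oxygens (distance criterion only)."""
    return _detect(system, _ch_donors(system),
                   _acceptor_oxygens(system, water_only=True),
                   r_max, None, conventional=False)


def profile_waters(system: MolecularSystem,
                   hbonds: list[HydrogenBond] | None = None,
                   ch_contacts: list[HydrogenBond] | None = None) -> list[WaterHBondProfile]:
    """Classify each water's bonding environment from detected bond lists.

    ``donated`` counts conventional bonds where the water is the donor,
    to any acceptor kind; ``accepted`` those where its oxygen accepts;
    CH contacts are kept apart.  Bond lists default to running the
    detectors with their default criteria.
    """
    if hbonds is None:
        hbonds = detect_hbonds(system)
    if ch_contacts is None:
        ch_contacts = detect_ch_contacts(system)
    profiles = []
    for mid, mol in enumerate(system.molecules):
        if mol.kind is not MoleculeKind.WATER:
            continue
        prof = WaterHBondProfile(water=mid, oh_lengths=system.water_oh_lengths(mid))
        for b in hbonds:
            if b.donor_mol == mid:
                prof.donated.append(b)
            if b.acceptor_mol == mid:
                prof.accepted.append(b)
        for b in ch_contacts:
            if b.acceptor_mol == mid:
                prof.ch_contacts.append(b)
        profiles.append(prof)
    return profiles
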