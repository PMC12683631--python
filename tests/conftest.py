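"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from o17shift.geometry_io import MolecularSystem, MoleculeKind
from o17shift.hbond_topology import HydrogenBond, WaterHBondProfile

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    from o17shift.shift_model import DEFAULT_PARAMS
    return DEFAULT_PARAMS


@pytest.fixture()
def dimer():
    from o17shift.synthetic_structures import make_dimer
    return make_dimer()


# ---------------------------------------------------------------------------
# independent all-pairs hydrogen-bond oracle
# ---------------------------------------------------------------------------

def brute_force_hbonds(system: MolecularSystem, r_max: float = 2.5,
                       angle_min: float | None = 150.0) -> set[tuple[int, int, int]]:
    """Plain O(n^2) enumeration of every (O-H, acceptor O) pair.

    Returns (donor_O, H, acceptor_O) triples; deliberately free of any
    neighbor-search machinery so it can serve as an oracle for the
    KD-tree based detector.
    """
    donors = []
    for i, j in system.covalent_bonds:
        els = {system.atoms[i].element, system.atoms[j].element}
        if els != {"O", "H"}:
            continue
        o, h = (i, j) if system.atoms[i].element == "O" else (j, i)
        if system.molecules[system.atoms[o].molecule_id].kind in (
                MoleculeKind.WATER, MoleculeKind.GLYCEROL):
            donors.append((o, h))
    acceptors = []
    for mid, mol in enumerate(system.molecules):
        for label, idx in mol.role_atoms.items():
            if label in ("water_O", "dmso_O") or label.startswith("hydroxyl_O"):
                acceptors.append((idx, mid))
    found = set()
    for o, h in donors:
        for a, amid in acceptors:
            if amid == system.atoms[o].molecule_id:
                continue
            r = np.linalg.norm(system.atoms[h].position - system.atoms[a].position)
            if r >= r_max:
                continue
            if angle_min is not None:
                v1 = system.atoms[o].position - system.atoms[h].position
                v2 = system.atoms[a].position - system.atoms[h].position
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(c, -1, 1))) <= angle_min:
                    continue
            found.add((o, h, a))
    return found


# ---------------------------------------------------------------------------
# randomized synthetic bonding profiles (no geometry involved)
# ---------------------------------------------------------------------------

def _bond(r: float, donor_kind: MoleculeKind, acceptor_kind: MoleculeKind,
          conventional: bool = True) -> HydrogenBond:
    return HydrogenBond(
        donor_heavy=0, hydrogen=1, acceptor_heavy=2, r_hb=float(r),
        angle_dha=165.0, donor_kind=donor_kind, acceptor_kind=acceptor_kind,
        donor_mol=0, acceptor_mol=1, conventional=conventional)


def random_profile(rng: np.random.Generator) -> WaterHBondProfile:
    """A random water bonding profile covering every interaction kind."""
    w = MoleculeKind.WATER
    prof = WaterHBondProfile(water=0)
    for _ in range(rng.integers(0, 3)):
        donor = MoleculeKind.GLYCEROL if rng.random() < 0.25 else w
        prof.accepted.append(_bond(rng.uniform(1.6, 2.4), donor, w))
    for _ in range(rng.integers(0, 3)):
        acc = w
        u = rng.random()
        if u < 0.2:
            acc = MoleculeKind.GLYCEROL
        elif u < 0.35:
            acc = MoleculeKind.DMSO
        prof.donated.append(_bond(rng.uniform(1.6, 2.4), w, acc))
    for _ in range(rng.integers(0, 3)):
        donor = MoleculeKind.DMSO if rng.random() < 0.5 else MoleculeKind.METHANE
        prof.ch_contacts.append(
            _bond(rng.uniform(2.2, 3.0), donor, w, conventional=False))
    prof.oh_lengths = (float(rng.uniform(0.96, 0.98)), float(rng.uniform(0.96, 0.98)))
    return prof


def direct_formula_shift(prof: WaterHBondProfile, bond_length_corrected: bool = False) -> float:
    """Hand-rolled evaluation of the published shift equations.

    Written with explicit literals, independently of the package's term
    functions, to serve as an oracle for ``calibrated_water_shift``.
    """
    water_sum = 0.0
    for b in prof.accepted:
        scale = 0.9 if b.donor_kind is MoleculeKind.GLYCEROL else 1.0
        water_sum += scale * 137.08 / b.r_hb ** 4
    n_donated = 0
    dmso_sum = 0.0
    for b in prof.donated:
        n_donated += 1
        if b.acceptor_kind is MoleculeKind.DMSO:
            dmso_sum += 270.49 / b.r_hb ** 6
        else:
            scale = 0.9 if b.acceptor_kind is MoleculeKind.GLYCEROL else 1.0
            water_sum += scale * 60.98 / b.r_hb ** 4
    ch_sum = sum(1799.10 / b.r_hb ** 6 for b in prof.ch_contacts)

    has_water_terms = water_sum != 0.0 or any(
        b.acceptor_kind is not MoleculeKind.DMSO for b in prof.donated
    ) or len(prof.accepted) > 0
    if not has_water_terms:
        return dmso_sum + ch_sum
    dangling = n_donated < 2
    if bond_length_corrected:
        blc = sum(579.36 / 2.0 * (r - 0.962) for r in prof.oh_lengths)
        scale = 0.95 if dangling else 1.12
        calibrated = scale * (water_sum + blc)
    elif dangling:
        calibrated = 1.20 * water_sum - 0.64
    else:
        calibrated = 1.38 * water_sum - 0.78
    return calibrated + dmso_sum + ch_sum
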