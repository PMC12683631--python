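"""Constructive generators for test geometries.

Everything downstream is exercised on structures built here: single
waters with prescribed internal geometry, the canonical water dimer
(H...O 1.71 A, O-H...O 163.7 deg, H...O-H 109.6 deg, donated O-H
stretched to 0.968 A), n-mers with an exact requested hydrogen-bond
topology around a central water, DMSO-water and methane-water
configurations, random water clusters and seeded pseudo-trajectories.

Requested geometric parameters are honoured exactly (to floating-point
round-off), so generator output doubles as an oracle: measuring the
produced coordinates must recover the request.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry_io import AtomRecord, MolecularSystem, MoleculeKind, assign_molecules
from .hbond_topology import detect_ch_contacts, detect_hbonds

__all__ = [
    "TopologySpec",
    "make_water",
    "make_dimer",
    "make_multimer",
    "make_dmso_water",
    "make_methane_water",
    "make_random_cluster",
    "perturb_trajectory",
]

R_OH_FREE = 0.962      # A, non-hydrogen-bonded covalent O-H
R_OH_DONATED = 0.968   # A, donated covalent O-H
HOH_ANGLE = 104.5      # deg; the shift is insensitive to ~10 deg changes here
HB_ANGLE_OHO = 163.7   # deg, O-H...O in the optimized dimer
HB_ANGLE_HOH = 109.6   # deg, H...O-H in the optimized dimer
R_HB_DIMER = 1.71      # A, H...O in the optimized dimer
TETRAHEDRAL = 109.47122063449069


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to unit vector u."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = _unit(ref - np.dot(ref, u) * u)
    return p, np.cross(u, p)


def _dir_at_angle(u: np.ndarray, theta_deg: float, spin_deg: float = 0.0) -> np.ndarray:
    """Unit vector at angle theta from u; spin sets the azimuth about u."""
    t, s = np.radians(theta_deg), np.radians(spin_deg)
    p, q = _perp_basis(u)
    return np.cos(t) * u + np.sin(t) * (np.cos(s) * p + np.sin(s) * q)


def _dir_pair(u: np.ndarray, theta_deg: float, mutual_deg: float,
              spin_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors, each at theta from u, separated by mutual_deg."""
    t = np.radians(theta_deg)
    cd = (np.cos(np.radians(mutual_deg)) - np.cos(t) ** 2) / np.sin(t) ** 2
    if abs(cd) > 1.0 + 1e-9:
        raise ValueError("incompatible angle pair requested")
    cd = float(np.clip(cd, -1.0, 1.0))
    half = np.degrees(np.arccos(cd)) / 2.0
    return (_dir_at_angle(u, theta_deg, spin_deg + half),
            _dir_at_angle(u, theta_deg, spin_deg - half))


def _bisecting_pair(u1: np.ndarray, u2: np.ndarray, theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """The two directions at equal angle theta from both u1 and u2 (lone pairs)."""
    c12 = float(np.dot(u1, u2))
    ct = np.cos(np.radians(theta_deg))
    alpha = ct / (1.0 + c12)
    v = _unit(np.cross(u1, u2))
    beta_sq = 1.0 - alpha ** 2 * (2.0 + 2.0 * c12)
    if beta_sq < 0:
        raise ValueError("no direction satisfies the requested angles")
    beta = np.sqrt(beta_sq)
    base = alpha * (u1 + u2)
    return base + beta * v, base - beta * v


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    axis = np.cross(u, v)
    s, c = np.linalg.norm(axis), float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        p, _ = _perp_basis(u)
        return Rotation.from_rotvec(np.pi * p).as_matrix()
    return Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()


def _place(coords: np.ndarray, anchor: np.ndarray, dir_from: np.ndarray,
           target: np.ndarray, dir_to: np.ndarray, spin_deg: float = 0.0) -> np.ndarray:
    """Rigidly move a template so anchor -> target and dir_from -> dir_to."""
    rot = _align_rotation(_unit(dir_from), _unit(dir_to))
    if spin_deg:
        rot = Rotation.from_rotvec(np.radians(spin_deg) * _unit(dir_to)).as_matrix() @ rot
    return (coords - anchor) @ rot.T + target


def _system(elements: Sequence[str], coords: np.ndarray, frame_id: int = 0) -> MolecularSystem:
    atoms = [AtomRecord(i, el, coords[i]) for i, el in enumerate(elements)]
    return assign_molecules(atoms, frame_id=frame_id)


# ---------------------------------------------------------------------------
# water, dimer, multimer
# ---------------------------------------------------------------------------

def _water_coords(r_oh1: float, r_oh2: float, hoh_angle: float) -> np.ndarray:
    a = np.radians(hoh_angle)
    return np.array([
        [0.0, 0.0, 0.0],
        [r_oh1, 0.0, 0.0],
        [r_oh2 * np.cos(a), r_oh2 * np.sin(a), 0.0],
    ])


def make_water(r_oh1: float = R_OH_FREE, r_oh2: float = R_OH_FREE,
               hoh_angle: float = HOH_ANGLE) -> MolecularSystem:
    """Planar water (atoms O, H1, H2) with the exact requested geometry."""
    if not (0.5 < r_oh1 < 1.5 and 0.5 < r_oh2 < 1.5):
        raise ValueError("O-H lengths must lie in (0.5, 1.5) A")
    if not 30.0 < hoh_angle < 180.0:
        raise ValueError("HOH angle must lie in (30, 180) deg")
    return _system(["O", "H", "H"], _water_coords(r_oh1, r_oh2, hoh_angle))


def make_dimer(r_hb: float = R_HB_DIMER, angle_ohO: float = HB_ANGLE_OHO,
               angle_hOh: float = HB_ANGLE_HOH, hoh_angle: float = HOH_ANGLE,
               r_oh_donated: float = R_OH_DONATED,
               r_oh_free: float = R_OH_FREE) -> MolecularSystem:
    """Water dimer: molecule 0 donates its H1 to molecule 1's oxygen.

    The donated O-H is stretched to 0.968 A; H...O distance, O-H...O
    angle and both H...O-H angles match the request exactly.
    """
    if r_hb <= 0:
        raise ValueError("hydrogen bond distance must be positive")
    xhat = np.array([1.0, 0.0, 0.0])
    o_d = np.zeros(3)
    h_don = np.array([r_oh_donated, 0.0, 0.0])
    h_d2 = r_oh_free * _dir_at_angle(xhat, hoh_angle, 90.0)  # +y side
    # acceptor O: angle O_d-H...O_a = angle_ohO at the donated H
    w = _dir_at_angle(xhat, 180.0 - angle_ohO, -90.0)        # bend to -y side
    o_a = h_don + r_hb * w
    # acceptor hydrogens: both at angle_hOh from the O_a -> H_don direction
    back = _unit(h_don - o_a)
    d1, d2 = _dir_pair(back, angle_hOh, hoh_angle)
    coords = np.array([o_d, h_don, h_d2, o_a, o_a + r_oh_free * d1, o_a + r_oh_free * d2])
    return _system(["O", "H", "H", "O", "H", "H"], coords)


@dataclass
class TopologySpec:
    """Requested bonding environment of a central water molecule.

    ``distances`` lists H...O distances for the accepted bonds first,
    then the donated ones; a scalar is broadcast.  ``partner_kinds``
    ('water' or 'glycerol', same ordering) defaults to all water.
    """

    n_accept: int
    n_donate: int
    distances: Sequence[float] | float = 1.70
    hb_angle: float = HB_ANGLE_OHO
    partner_kinds: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_accept <= 2 and 0 <= self.n_donate <= 2):
            raise ValueError("a water accepts and donates at most 2 bonds each")
        if self.n_accept + self.n_donate > 4:
            raise ValueError("at most 4 hydrogen bonds per water")
        n = self.n_accept + self.n_donate
        if np.isscalar(self.distances):
            self.distances = [float(self.distances)] * n
        self.distances = [float(d) for d in self.distances]
        if len(self.distances) != n:
            raise ValueError(f"expected {n} distances, got {len(self.distances)}")
        if any(not 1.4 < d < 3.5 for d in self.distances):
            raise ValueError("hydrogen bond distances must lie in (1.4, 3.5) A")
        if self.partner_kinds is None:
            self.partner_kinds = ["water"] * n
        self.partner_kinds = [str(k) for k in self.partner_kinds]
        if len(self.partner_kinds) != n:
            raise ValueError(f"expected {n} partner kinds")
        if any(k not in ("water", "glycerol") for k in self.partner_kinds):
            raise ValueError("partner kinds must be 'water' or 'glycerol'")

    @classmethod
    def from_string(cls, text: str) -> "TopologySpec":
        """Parse shorthand like ``'2A1D'`` or ``'1A2D@1.75'``."""
        m = re.fullmatch(r"(?:(\d)A)?(?:(\d)D)?(?:@([\d.]+))?", text.strip())
        if not m or (m.group(1) is None and m.group(2) is None):
            raise ValueError(f"cannot parse topology spec {text!r}")
        na = int(m.group(1) or 0)
        nd = int(m.group(2) or 0)
        dist = float(m.group(3)) if m.group(3) else 1.70
        return cls(n_accept=na, n_donate=nd, distances=dist)


def _multimer_once(spec: TopologySpec, spins: np.ndarray) -> MolecularSystem:
    """One construction attempt; ``spins`` supplies all free azimuths."""
    xhat = np.array([1.0, 0.0, 0.0])
    u1, u2 = xhat, _dir_at_angle(xhat, HOH_ANGLE, 90.0)
    len1 = R_OH_DONATED if spec.n_donate >= 1 else R_OH_FREE
    len2 = R_OH_DONATED if spec.n_donate >= 2 else R_OH_FREE
    elements = ["O", "H", "H"]
    coords = [np.zeros(3), len1 * u1, len2 * u2]
    glyc = _glycerol_template()
    si = iter(spins)

    def add_water(o: np.ndarray, h1: np.ndarray, h2: np.ndarray) -> None:
        elements.extend(["O", "H", "H"])
        coords.extend([o, h1, h2])

    def add_glycerol(placed: np.ndarray) -> None:
        elements.extend(glyc.elements)
        coords.extend(placed)

    lps = _bisecting_pair(u1, u2, TETRAHEDRAL)
    for k in range(spec.n_accept):
        r = spec.distances[k]
        lp = lps[k]
        h_pos = r * lp
        # donor heavy atom set so the donor-H...acceptor angle equals hb_angle
        v = _dir_at_angle(lp, 180.0 - spec.hb_angle, next(si))
        if spec.partner_kinds[k] == "water":
            o_d = h_pos + R_OH_DONATED * v
            h2 = o_d + R_OH_FREE * _dir_at_angle(_unit(h_pos - o_d), HOH_ANGLE, next(si))
            add_water(o_d, h_pos, h2)
        else:
            o_idx, h_idx = glyc.hydroxyls[0]
            placed = _place(glyc.coords, glyc.coords[h_idx],
                            glyc.coords[o_idx] - glyc.coords[h_idx],
                            h_pos, v, next(si))
            add_glycerol(placed)

    for j in range(spec.n_donate):
        r = spec.distances[spec.n_accept + j]
        u = (u1, u2)[j]
        h_pos = R_OH_DONATED * u
        w = _dir_at_angle(u, 180.0 - spec.hb_angle, next(si))
        o_a = h_pos + r * w
        back = _unit(h_pos - o_a)
        if spec.partner_kinds[spec.n_accept + j] == "water":
            d1, d2 = _dir_pair(back, HB_ANGLE_HOH, HOH_ANGLE, next(si))
            add_water(o_a, o_a + R_OH_FREE * d1, o_a + R_OH_FREE * d2)
        else:
            o_idx, h_idx = glyc.hydroxyls[0]
            d_h = _dir_at_angle(back, HB_ANGLE_HOH, next(si))
            placed = _place(glyc.coords, glyc.coords[o_idx],
                            glyc.coords[h_idx] - glyc.coords[o_idx],
                            o_a, d_h, next(si))
            add_glycerol(placed)
    return _system(elements, np.array(coords))


def _multimer_ok(spec: TopologySpec, system: MolecularSystem) -> bool:
    r_max = max(2.5, max(spec.distances, default=0.0) + 0.05)
    angle_min = min(150.0, spec.hb_angle - 1.0)
    bonds = detect_hbonds(system, r_max=r_max, angle_min=angle_min)
    accepted = [b for b in bonds if b.acceptor_mol == 0]
    donated = [b for b in bonds if b.donor_mol == 0]
    if len(bonds) != spec.n_accept + spec.n_donate:
        return False  # spurious neighbor-neighbor bonds
    if len(accepted) != spec.n_accept or len(donated) != spec.n_donate:
        return False
    want_acc = sorted(zip(spec.distances[:spec.n_accept],
                          spec.partner_kinds[:spec.n_accept]))
    got_acc = sorted((b.r_hb, b.donor_kind.value) for b in accepted)
    want_don = sorted(zip(spec.distances[spec.n_accept:],
                          spec.partner_kinds[spec.n_accept:]))
    got_don = sorted((b.r_hb, b.acceptor_kind.value) for b in donated)
    for want, got in ((want_acc, got_acc), (want_don, got_don)):
        for (rw, kw), (rg, kg) in zip(want, got):
            if abs(rw - rg) > 1e-6 or kw != kg:
                return False
    # glycerol neighbors must not add CH...O contacts onto the central water
    if any(c.acceptor_mol == 0 for c in detect_ch_contacts(system)):
        return False
    return True


def make_multimer(spec: TopologySpec, seed: int = 0, max_retries: int = 50) -> MolecularSystem:
    """Cluster with a central water (molecule 0) of exact requested topology.

    Neighbor placement has free azimuths; attempts are retried with new
    seeded azimuths until the detector confirms exactly the requested
    bond set and nothing else, or ``max_retries`` is exhausted.
    """
    rng = np.random.default_rng(seed)
    n_spins = 3 * (spec.n_accept + spec.n_donate) + 2
    for attempt in range(max_retries):
        spins = (np.zeros(n_spins) if attempt == 0
                 else rng.uniform(0.0, 360.0, n_spins))
        try:
            system = _multimer_once(spec, spins)
        except Exception:
            continue
        if _multimer_ok(spec, system):
            return system
    raise RuntimeError(
        f"could not realize topology {spec.n_accept}A{spec.n_donate}D "
        f"without spurious contacts after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# DMSO / glycerol / methane fixtures
# ---------------------------------------------------------------------------

@dataclass
class _Template:
    elements: list[str]
    coords: np.ndarray
    hydroxyls: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _methyl_dirs(u_cs: np.ndarray) -> list[np.ndarray]:
    """Three C-H directions of a methyl whose C-S bond points along u_cs."""
    p, q = _perp_basis(u_cs)
    out = []
    for phi in (0.0, 120.0, 240.0):
        a = np.radians(phi)
        out.append(-u_cs / 3.0 + np.sqrt(8.0) / 3.0 * (np.cos(a) * p + np.sin(a) * q))
    return out


def _dmso_template() -> _Template:
    """Rigid DMSO: S=O 1.50 A, S-C 1.80 A, C-S-C 97 deg, one H per methyl up."""
    s = np.zeros(3)
    o = np.array([0.0, 0.0, 1.50])
    alpha = np.radians(107.0)
    cos_dphi = (np.cos(np.radians(97.0)) - np.cos(alpha) ** 2) / np.sin(alpha) ** 2
    half = np.arccos(cos_dphi) / 2.0
    cs = []
    for sgn in (1.0, -1.0):
        cs.append(1.80 * np.array([np.sin(alpha) * np.cos(sgn * half),
                                   np.sin(alpha) * np.sin(sgn * half),
                                   np.cos(alpha)]))
    elements = ["S", "O", "C", "C"]
    coords = [s, o, cs[0], cs[1]]
    up_h = []
    for c in cs:
        dirs = _methyl_dirs(_unit(s - c))
        up_h.append(len(coords))  # phi=0 points toward +z
        for d in dirs:
            elements.append("H")
            coords.append(c + 1.09 * d)
    return _Template(elements, np.array(coords), meta={"S": 0, "O": 1, "up_H": up_h})


def _glycerol_template() -> _Template:
    """Rigid idealized glycerol (C3H8O3): tetrahedral backbone, 3 hydroxyls."""
    th = TETRAHEDRAL
    xhat = np.array([1.0, 0.0, 0.0])
    c1 = np.zeros(3)
    c2 = np.array([1.52, 0.0, 0.0])
    d23 = _dir_at_angle(-xhat, th, 90.0)
    c3 = c2 + 1.52 * d23
    # C2 substituents from the two backbone bonds
    sub_a, sub_b = _bisecting_pair(_unit(c1 - c2), _unit(c3 - c2), th)
    if sub_a[2] < sub_b[2]:
        sub_a, sub_b = sub_b, sub_a
    o2 = c2 + 1.43 * sub_a
    h_c2 = c2 + 1.09 * sub_b
    # terminal carbons: three tetrahedral directions each
    o1 = c1 + 1.43 * _dir_at_angle(xhat, th, 90.0)
    h_c1a = c1 + 1.09 * _dir_at_angle(xhat, th, 210.0)
    h_c1b = c1 + 1.09 * _dir_at_angle(xhat, th, 330.0)
    u3 = _unit(c2 - c3)
    o3 = c3 + 1.43 * _dir_at_angle(u3, th, 90.0)
    h_c3a = c3 + 1.09 * _dir_at_angle(u3, th, 210.0)
    h_c3b = c3 + 1.09 * _dir_at_angle(u3, th, 330.0)
    # hydroxyl hydrogens, pointing away from the backbone
    h_o1 = o1 + 0.96 * _dir_at_angle(_unit(c1 - o1), 108.0, 90.0)
    h_o2 = o2 + 0.96 * _dir_at_angle(_unit(c2 - o2), 108.0, 0.0)
    h_o3 = o3 + 0.96 * _dir_at_angle(_unit(c3 - o3), 108.0, 90.0)
    elements = ["C", "C", "C", "O", "O", "O",
                "H", "H", "H", "H", "H", "H", "H", "H"]
    coords = np.array([c1, c2, c3, o1, o2, o3,
                       h_c1a, h_c1b, h_c2, h_c3a, h_c3b, h_o1, h_o2, h_o3])
    return _Template(elements, coords, hydroxyls=[(3, 11), (4, 12), (5, 13)])


def _water_rigid(params6: np.ndarray, local: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(params6[3:]).as_matrix()
    return local @ rot.T + params6[:3]


def make_dmso_water(conf: int, r_os: float = 1.8, r_ch: float = 2.6) -> MolecularSystem:
    """Water next to a rigid DMSO in one of three interaction patterns.

    conf 1: water donates to the S=O oxygen (H...O = ``r_os``) and its
    oxygen sits ``r_ch`` from one hydrogen of each methyl group;
    conf 2: donation plus a single methyl contact; conf 3: two methyl
    contacts only.  Water orientation is solved numerically; the
    detector is used to verify the resulting pattern.
    """
    if conf not in (1, 2, 3):
        raise ValueError("conf must be 1, 2 or 3")
    dmso = _dmso_template()
    o_d = dmso.coords[dmso.meta["O"]]
    hu1 = dmso.coords[dmso.meta["up_H"][0]]
    hu2 = dmso.coords[dmso.meta["up_H"][1]]
    other_h = [dmso.coords[i] for i in range(4, 10) if i not in dmso.meta["up_H"]]
    donated = conf in (1, 2)
    local = _water_coords(R_OH_DONATED if donated else R_OH_FREE, R_OH_FREE, HOH_ANGLE)

    def residuals(p: np.ndarray) -> np.ndarray:
        w = _water_rigid(p, local)
        ow, h1, h2 = w
        res = []
        if donated:
            res.append(np.linalg.norm(h1 - o_d) - r_os)
            # keep the donated bond near-linear and the free H away
            vec_o = ow - h1
            vec_a = o_d - h1
            cang = np.dot(vec_o, vec_a) / (np.linalg.norm(vec_o) * np.linalg.norm(vec_a))
            ang = np.degrees(np.arccos(np.clip(cang, -1, 1)))
            res.append(max(0.0, 155.0 - ang) * 0.05)
            res.append(max(0.0, 2.55 - np.linalg.norm(h2 - o_d)))
        else:
            res.append(max(0.0, 2.55 - np.linalg.norm(h1 - o_d)))
            res.append(max(0.0, 2.55 - np.linalg.norm(h2 - o_d)))
        if conf in (1, 3):
            res.append(np.linalg.norm(ow - hu1) - r_ch)
            res.append(np.linalg.norm(ow - hu2) - r_ch)
        else:
            res.append(np.linalg.norm(ow - hu1) - r_ch)
            res.append(max(0.0, 3.05 - np.linalg.norm(ow - hu2)))
        for h in other_h:
            res.append(max(0.0, 3.02 - np.linalg.norm(ow - h)))
        return np.array(res)

    if conf == 1:
        start = np.array([2.3, 0.0, 1.6, 0.0, 0.0, 0.0])
        rot0 = _align_rotation(np.array([1.0, 0, 0]), _unit(o_d - start[:3]))
        start[3:] = Rotation.from_matrix(rot0).as_rotvec()
    elif conf == 2:
        start = np.array([2.2, 1.3, 1.3, 0.0, 0.0, 0.0])
        rot0 = _align_rotation(np.array([1.0, 0, 0]), _unit(o_d - start[:3]))
        start[3:] = Rotation.from_matrix(rot0).as_rotvec()
    else:
        start = np.array([3.2, 0.0, 1.0, 0.0, 0.0, 0.0])

    best = None
    for attempt in range(16):
        p0 = start if attempt == 0 else start + np.random.default_rng(attempt).normal(0, 0.5, 6)
        sol = least_squares(residuals, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if best.cost > 1e-10:
        raise RuntimeError(f"could not realize DMSO-water conf{conf} "
                           f"(residual {best.cost:.2e})")
    water = _water_rigid(best.x, local)
    system = _system(dmso.elements + ["O", "H", "H"],
                     np.vstack([dmso.coords, water]))
    n_conv = len(detect_hbonds(system))
    n_ch = len(detect_ch_contacts(system))
    expect = {1: (1, 2), 2: (1, 1), 3: (0, 2)}[conf]
    if (n_conv, n_ch) != expect:
        raise RuntimeError(
            f"conf{conf} produced {n_conv} conventional bonds and {n_ch} CH "
            f"contacts; expected {expect}")
    return system


def make_methane_water(r: float = 2.6) -> MolecularSystem:
    """Methane with one C-H pointing at a water oxygen at distance ``r``."""
    if r <= 0:
        raise ValueError("distance must be positive")
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
    c = np.zeros(3)
    hs = 1.09 * dirs
    u = dirs[0]
    ow = hs[0] + r * u
    d1, d2 = _dir_pair(u, HOH_ANGLE / 2.0, HOH_ANGLE)  # both H point away
    coords = np.vstack([c, hs, ow, ow + R_OH_FREE * d1, ow + R_OH_FREE * d2])
    return _system(["C", "H", "H", "H", "H", "O", "H", "H"], coords)


# ---------------------------------------------------------------------------
# random clusters and trajectories
# ---------------------------------------------------------------------------

def make_random_cluster(n_waters: int, seed: int = 0, min_oo: float = 2.4,
                        box_scale: float = 3.1) -> MolecularSystem:
    """Randomly placed and oriented waters in a cube (seeded).

    Oxygen positions keep at least ``min_oo`` A apart so hydrogens stay
    uniquely assignable; the box side scales with n^(1/3) to keep the
    density roughly liquid-like, giving a realistic mix of bonded and
    non-bonded pairs.
    """
    rng = np.random.default_rng(seed)
    side = max(box_scale * n_waters ** (1.0 / 3.0), 2.0 * min_oo)
    oxygens: list[np.ndarray] = []
    tries = 0
    while len(oxygens) < n_waters:
        cand = rng.uniform(0.0, side, 3)
        if all(np.linalg.norm(cand - o) >= min_oo for o in oxygens):
            oxygens.append(cand)
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place waters; lower min_oo or n_waters")
    local = _water_coords(R_OH_FREE, R_OH_FREE, HOH_ANGLE)
    elements, coords = [], []
    for o in oxygens:
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        elements.extend(["O", "H", "H"])
        coords.extend(local @ rot.T + o)
    return _system(elements, np.array(coords))


def perturb_trajectory(system: MolecularSystem, n_frames: int, amplitude: float,
                       seed: int = 0) -> list[MolecularSystem]:
    """Seeded Gaussian displacements standing in for MD snapshots.

    After displacing every atom, each covalent X-H bond is re-projected
    onto its original length, so internal O-H (and C-H) distances are
    rigid while hydrogen-bond geometry fluctuates.  Deterministic for a
    given seed; amplitude 0 reproduces the input exactly.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    ref = system.positions
    bond_lengths = {
        (i, j): system.distance(i, j) for i, j in system.covalent_bonds
    }
    frames = []
    for f in range(n_frames):
        pos = ref + rng.normal(0.0, amplitude, ref.shape)
        for (i, j), r0 in bond_lengths.items():
            if system.atoms[j].element == "H":
                heavy, h = i, j
            elif system.atoms[i].element == "H":
                heavy, h = j, i
            else:
                continue
            v = pos[h] - pos[heavy]
            pos[h] = pos[heavy] + r0 * v / np.linalg.norm(v)
        frames.append(system.copy_with_positions(pos, frame_id=f))
    return frames
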