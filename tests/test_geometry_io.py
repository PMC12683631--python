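"""Structure parsing, covalent assignment and molecule typing."""

import math

import numpy as np
import pytest

from o17shift.geometry_io import (
    AmbiguousHydrogenError,
    AtomRecord,
    MoleculeKind,
    ParseError,
    assign_molecules,
    read_pdb,
    read_xyz,
    write_xyz,
)
from o17shift.shift_model import predict_shifts
from o17shift.synthetic_structures import (
    make_dimer,
    make_methane_water,
    make_multimer,
    make_random_cluster,
    TopologySpec,
)

WATER_XYZ = """3
one water
O 0.000000 0.000000 0.000000
H 0.962000 0.000000 0.000000
H -0.240900 0.931300 0.000000
"""


def test_minimal_xyz_single_frame(tmp_path):
    p = tmp_path / "w.xyz"
    p.write_text(WATER_XYZ)
    frames = read_xyz(p)
    assert len(frames) == 1
    assert frames[0].n_atoms == 3
    assert [m.kind for m in frames[0].molecules] == [MoleculeKind.WATER]


def test_concatenated_blocks_become_frames(tmp_path):
    p = tmp_path / "t.xyz"
    write_xyz([make_dimer(), make_dimer()], p)
    frames = read_xyz(p)
    assert len(frames) == 2
    assert all(f.n_atoms == 6 for f in frames)
    assert [f.frame_id for f in frames] == [0, 1]


def test_dimer_oo_distance_matches_trigonometry(tmp_path):
    # law of cosines at the donated H: O-H=0.968, H...O=1.71, angle 163.7 deg
    expected = math.sqrt(
        0.968**2 + 1.71**2 - 2 * 0.968 * 1.71 * math.cos(math.radians(163.7))
    )
    p = tmp_path / "d.xyz"
    write_xyz(make_dimer(), p)
    sys_ = read_xyz(p)[0]
    assert sys_.n_atoms == 6
    assert sys_.distance(0, 3) == pytest.approx(expected, abs=5e-6)


def test_write_read_round_trip_to_six_decimals(tmp_path):
    sys_ = make_multimer(TopologySpec(2, 1, 1.8), seed=4)
    p = tmp_path / "m.xyz"
    write_xyz(sys_, p)
    back = read_xyz(p)[0]
    assert np.abs(back.positions - sys_.positions).max() < 1e-6
    assert [m.kind for m in back.molecules] == [m.kind for m in sys_.molecules]


@pytest.mark.parametrize("content,line", [
    ("banana\ncomment\nO 0 0 0\n", 1),                        # bad count line
    ("1\nc\nO zero 0 0\n", 3),                                # non-numeric coord
    ("4\nc\nO 0 0 0\nH 1 0 0\nH 0 1 0\n", 1),                 # truncated frame
    ("1\nc\nQq 0 0 0\n", 3),                                  # unknown element
])
def test_malformed_xyz_raises_with_line_number(tmp_path, content, line):
    p = tmp_path / "bad.xyz"
    p.write_text(content)
    with pytest.raises(ParseError, match=f"line {line}"):
        read_xyz(p)


def _pdb_atom(serial, name, res, resseq, pos, element, het=False):
    rec = "HETATM" if het else "ATOM  "
    x, y, z = pos
    return (f"{rec}{serial:>5d} {name:<4s}{res:<4s}A{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def test_pdb_water_and_formula_overriding_name(tmp_path):
    lines = [
        _pdb_atom(1, "O", "HOH", 1, (0, 0, 0), "O"),
        _pdb_atom(2, "H1", "HOH", 1, (0.962, 0, 0), "H"),
        _pdb_atom(3, "H2", "HOH", 1, (-0.24, 0.93, 0), "H"),
        # residue named XYZ but clearly H2O by formula/connectivity
        _pdb_atom(4, "O", "XYZ", 2, (8, 0, 0), "O", het=True),
        _pdb_atom(5, "H1", "XYZ", 2, (8.962, 0, 0), "H", het=True),
        _pdb_atom(6, "H2", "XYZ", 2, (7.76, 0.93, 0), "H", het=True),
        "END",
    ]
    p = tmp_path / "w.pdb"
    p.write_text("\n".join(lines) + "\n")
    sys_ = read_pdb(p)[0]
    assert [m.kind for m in sys_.molecules] == [MoleculeKind.WATER, MoleculeKind.WATER]


def test_pdb_dms_residue_typed_dmso(tmp_path):
    from o17shift.synthetic_structures import _dmso_template
    t = _dmso_template()
    lines = [
        _pdb_atom(i + 1, f"{el}{i}", "DMS", 1, tuple(t.coords[i]), el, het=True)
        for i, el in enumerate(t.elements)
    ] + ["END"]
    p = tmp_path / "d.pdb"
    p.write_text("\n".join(lines) + "\n")
    sys_ = read_pdb(p)[0]
    assert [m.kind for m in sys_.molecules] == [MoleculeKind.DMSO]
    s = sys_.molecules[0].role_atoms["dmso_S"]
    o = sys_.molecules[0].role_atoms["dmso_O"]
    assert sys_.distance(s, o) == pytest.approx(1.50, abs=1e-3)


def test_atom_order_permutation_changes_nothing():
    sys_ = make_multimer(TopologySpec(1, 1, 1.75), seed=7)
    rng = np.random.default_rng(0)
    perm = rng.permutation(sys_.n_atoms)
    atoms = [AtomRecord(k, sys_.atoms[i].element, sys_.atoms[i].position)
             for k, i in enumerate(perm)]
    shuffled = assign_molecules(atoms)
    assert sorted(m.kind for m in shuffled.molecules) == sorted(
        m.kind for m in sys_.molecules)
    # bond sets agree as unordered pairs after mapping through the permutation
    inv = {int(old): new for new, old in enumerate(perm)}
    mapped = {frozenset((inv[a], inv[b])) for a, b in sys_.covalent_bonds}
    assert mapped == {frozenset(b) for b in shuffled.covalent_bonds}
    # downstream shifts agree water-by-water (matched via oxygen position)
    def by_o_position(system):
        out = {}
        for bd in predict_shifts(system):
            o = system.molecules[bd.water].role_atoms["water_O"]
            out[tuple(np.round(system.atoms[o].position, 6))] = bd.delta_isolated_ref
        return out
    a, b = by_o_position(sys_), by_o_position(shuffled)
    assert a.keys() == b.keys()
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-9)


def test_hydrogen_between_two_oxygens_is_ambiguous():
    atoms = [
        AtomRecord(0, "O", np.array([0.0, 0.0, 0.0])),
        AtomRecord(1, "H", np.array([1.0, 0.0, 0.0])),
        AtomRecord(2, "O", np.array([2.0, 0.0, 0.0])),
    ]
    with pytest.raises(AmbiguousHydrogenError, match="H2"):
        assign_molecules(atoms)


def test_lone_hydrogen_warns_and_is_flagged():
    atoms = [
        AtomRecord(0, "O", np.array([0.0, 0.0, 0.0])),
        AtomRecord(1, "H", np.array([0.962, 0.0, 0.0])),
        AtomRecord(2, "H", np.array([-0.24, 0.93, 0.0])),
        AtomRecord(3, "H", np.array([9.0, 9.0, 9.0])),
    ]
    with pytest.warns(UserWarning, match="no covalent partner"):
        sys_ = assign_molecules(atoms)
    kinds = sorted(m.kind.value for m in sys_.molecules)
    assert kinds == ["other", "water"]


def test_methane_plus_water_typing():
    sys_ = make_methane_water(2.6)
    assert sorted(m.kind.value for m in sys_.molecules) == ["methane", "water"]


def test_every_hydrogen_covalently_assigned_once():
    sys_ = make_random_cluster(15, seed=11)
    for a in sys_.atoms:
        if a.element != "H":
            continue
        partners = sys_.covalent_neighbors(a.index)
        assert len(partners) == 1
        assert sys_.atoms[partners[0]].element == "O"
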