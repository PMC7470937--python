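"""Structure I/O, bond inference and symmetry expansion."""

import numpy as np
import pytest

from pairdex.errors import EmptyStructureError, NoSymmetryError
from pairdex.fixtures import ideal_base
from pairdex.structure_io import (
    Atom,
    CrystalStructure,
    UnitCell,
    expand_symmetry,
    infer_bonds,
    read_structure,
    write_structure,
)


def _atom(label, element, x, y, z, **kw):
    return Atom(label, element, np.array([x, y, z], dtype=float), **kw)


# ---------------------------------------------------------------------------
# reading / writing


def test_cif_round_trip(tmp_path, catalog_by_name):
    s = catalog_by_name["AA_mWW_(16)(61)"].structure
    path = write_structure(s, tmp_path / "pair.cif", format="cif")
    back = read_structure(path)
    assert [a.element for a in back.atoms] == [a.element for a in s.atoms]
    assert np.allclose(back.coords(), s.coords(), atol=1e-3)
    # dummy P1 box emitted for the cell-less structure
    assert back.cell is not None and back.cell.symops == ["x,y,z"]


def test_pdb_round_trip(tmp_path, catalog_by_name):
    s = catalog_by_name["UU_mWW_(34)(43)"].structure
    path = write_structure(s, tmp_path / "pair.pdb", format="pdb")
    back = read_structure(path)
    assert back.cell is None  # no CRYST1 written for a cell-less structure
    assert np.allclose(back.coords(), s.coords(), atol=1e-3)


def test_empty_structure_refused(tmp_path):
    with pytest.raises(EmptyStructureError):
        write_structure(CrystalStructure("x", None, []), tmp_path / "x.cif")


def test_cif_disorder_keeps_major_part(tmp_path):
    cif = """data_dis
_cell_length_a 20.0
_cell_length_b 20.0
_cell_length_c 20.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
_atom_site_disorder_group
C1 C 0.10 0.10 0.10 1.00 .
O1A O 0.20 0.10 0.10 0.70 1
O1B O 0.10 0.20 0.10 0.30 2
"""
    p = tmp_path / "dis.cif"
    p.write_text(cif)
    s = read_structure(p)
    assert [a.label for a in s.atoms] == ["C1", "O1A"]
    assert s.atoms[1].occupancy == pytest.approx(0.7)


def test_cif_explicit_bond_table_used_verbatim(tmp_path):
    cif = """data_b
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.0 0.0 0.0
N1 N 0.5 0.5 0.5
loop_
_geom_bond_atom_site_label_1
_geom_bond_atom_site_label_2
C1 N1
"""
    p = tmp_path / "b.cif"
    p.write_text(cif)
    s = read_structure(p)
    assert s.bonds == [(0, 1)]
    # inference does not overwrite the explicit table
    infer_bonds(s)
    assert s.bonds == [(0, 1)]


# ---------------------------------------------------------------------------
# bond inference


def test_infer_bonds_covalent_radius_rule():
    s = CrystalStructure("t", None, [
        _atom("C1", "C", 0, 0, 0),
        _atom("N1", "N", 1.34, 0, 0),
        _atom("N2", "N", 1.34, 2.9, 0),
    ])
    infer_bonds(s)
    assert (0, 1) in s.bonds          # 1.34 <= 0.76 + 0.71 + 0.4
    assert (1, 2) not in s.bonds      # 2.9 A is a contact, not a bond


def test_hydrogen_bonds_to_nearest_heavy_only():
    s = CrystalStructure("t", None, [
        _atom("N1", "N", 0, 0, 0),
        _atom("N2", "N", 2.9, 0, 0),
        _atom("H1", "H", 1.0, 0, 0),  # 1.0 from N1, 1.9 from N2
    ])
    infer_bonds(s)
    assert (0, 2) in s.bonds
    assert (1, 2) not in s.bonds


def test_orphan_hydrogen_dropped_with_warning():
    s = CrystalStructure("t", None, [
        _atom("C1", "C", 0, 0, 0),
        _atom("H9", "H", 5.0, 0, 0),
    ])
    with pytest.warns(UserWarning, match="hydrogen"):
        infer_bonds(s)
    assert len(s.atoms) == 1


# ---------------------------------------------------------------------------
# symmetry expansion


def _p1_structure(base_code="U", cell_len=8.0):
    """One free base in a deliberately small P1 cell: translational images
    fall inside the contact envelope."""
    inst = ideal_base(base_code, "free", "1H 3H")
    src = inst.structure
    cell = UnitCell(cell_len, 20.0, 20.0, 90.0, 90.0, 90.0)
    atoms = [a.copy() for a in src.atoms]
    for a in atoms:
        a.frac = cell.fractionalize(a.xyz)
    return CrystalStructure("p1", cell, atoms, bonds=list(src.bonds))


def test_expand_symmetry_p1_matches_brute_force():
    s = _p1_structure()
    n_asu = len(s.atoms)
    radius = 6.0
    expand_symmetry(s, radius=radius)
    mates = {a.source_op for a in s.atoms if a.is_symmetry_mate}
    # brute force: which +-1/+-2 translations put any atom within the radius?
    asu = s.coords()[:n_asu]
    expected = set()
    cell = s.cell
    for ta in range(-2, 3):
        for tb in range(-1, 2):
            for tc in range(-1, 2):
                if (ta, tb, tc) == (0, 0, 0):
                    continue
                shift = ta * np.array([cell.a, 0, 0]) + tb * np.array([0, cell.b, 0]) \
                    + tc * np.array([0, 0, cell.c])
                moved = asu + shift
                d = np.sqrt(((moved[:, None, :] - asu[None, :, :]) ** 2).sum(-1)).min()
                if d <= radius:
                    expected.add((ta, tb, tc))
    got = set()
    for op in mates:
        trans = op.split("+")[1].strip("()")
        got.add(tuple(int(x) for x in trans.split(",")))
    assert got == expected and len(expected) >= 2


def test_expand_symmetry_idempotent_and_radius_zero():
    s = _p1_structure()
    expand_symmetry(s, radius=6.0)
    n = len(s.atoms)
    expand_symmetry(s, radius=6.0)
    assert len(s.atoms) == n

    s2 = _p1_structure()
    expand_symmetry(s2, radius=0.0)
    assert all(not a.is_symmetry_mate for a in s2.atoms)


def test_expand_without_cell_raises(catalog_by_name):
    s = catalog_by_name["AA_mWW_(16)(61)"].structure
    assert s.cell is None
    with pytest.raises(NoSymmetryError):
        expand_symmetry(s)
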