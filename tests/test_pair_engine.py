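"""Hydrogen-bond criteria, pair detection, geometry and D-H normalization."""

import dataclasses

import numpy as np
import pytest

from pairdex.base_recognition import find_bases
from pairdex.chem_templates import DEFAULT_PARAMS, donor_acceptor_roles
from pairdex.fixtures import ideal_base, _unit
from pairdex.pair_engine import (
    base_plane,
    detect_hbonds,
    detect_pairs,
    normalize_dh,
    pair_geometry,
)
from pairdex.structure_io import Atom, CrystalStructure, UnitCell, infer_bonds


def _translated_copy(inst, shift):
    """Second instance of the same ideal base, rigidly translated."""
    src = inst.structure
    atoms = [a.copy() for a in src.atoms]
    for a in atoms:
        a.xyz = a.xyz + np.asarray(shift, dtype=float)
    merged = CrystalStructure(
        "two", None, [a.copy() for a in src.atoms] + atoms
    )
    infer_bonds(merged)
    b1, b2 = find_bases(merged)
    return b1, b2


# ---------------------------------------------------------------------------
# planes


def test_base_plane_face_label():
    inst = ideal_base("A", "free", "1 3 7 9H")
    _, n = base_plane(inst)
    assert abs(abs(n[2]) - 1.0) < 1e-9
    sign = n[2]
    # mirroring the base through y -> -y reverses the ring circuit sense
    src = inst.structure
    for a in src.atoms:
        a.xyz = a.xyz * np.array([1.0, -1.0, 1.0])
    (flipped,) = find_bases(src)
    assert base_plane(flipped)[1][2] == pytest.approx(-sign)


def test_base_plane_with_pucker_noise():
    inst = ideal_base("G", "free", "1H 3 7 9H")
    rng = np.random.default_rng(3)
    src = inst.structure
    for a in src.atoms:
        a.xyz = a.xyz + np.array([0.0, 0.0, rng.normal(0.0, 0.1)])
    (noisy,) = find_bases(src)
    _, n = base_plane(noisy)
    # SVD oracle on the same ring coordinates
    pts = noisy.ring_xyz()
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    assert abs(np.dot(n, vt[2])) > 0.999
    assert abs(n[2]) > 0.99


# ---------------------------------------------------------------------------
# hydrogen-bond criteria


def test_nh_n_contact_within_threshold_accepted():
    inst = ideal_base("A", "R", "1H 3 7 9R")  # N1-H donor
    n1, n7 = inst.xyz(1), inst.xyz(7)
    # slide the second base so its N7 sits 2.9 A from N1 along the N1-H line
    h = inst.structure.atoms[inst.attached_h(1)[0]].xyz
    target = inst.xyz(1) + _unit(h - n1) * 2.9
    b1, b2 = _translated_copy(inst, target - n7)
    bonds = detect_hbonds(b1, b2)
    found = {(hb.d_atom, hb.a_atom, hb.bond_class) for hb in bonds}
    assert (1, 7, "NH...N") in found
    hb = next(h for h in bonds if (h.d_atom, h.a_atom) == (1, 7))
    assert hb.d_a == pytest.approx(2.9, abs=1e-6)
    assert hb.dha > 170


def test_contact_beyond_vdw_margin_rejected():
    inst = ideal_base("A", "R", "1H 3 7 9R")
    n1, n7 = inst.xyz(1), inst.xyz(7)
    h = inst.structure.atoms[inst.attached_h(1)[0]].xyz
    # N...N bound is 1.55 + 1.55 + 1.0 = 4.10 A; 4.5 A must fail
    target = n1 + _unit(h - n1) * 4.5
    b1, b2 = _translated_copy(inst, target - n7)
    assert all((hb.d_atom, hb.a_atom) != (1, 7) for hb in detect_hbonds(b1, b2))


def test_low_dha_ch_contact_rejected():
    """A C-H...O contact at 105 deg fails the 120 deg angle floor."""
    inst = ideal_base("Hx", "R", "1H 3 7 9R")
    c8 = inst.xyz(8)
    h8 = inst.structure.atoms[inst.attached_h(8)[0]].xyz
    u = _unit(h8 - c8)
    perp = _unit(np.cross(np.array([0.0, 0.0, 1.0]), u))
    # acceptor placed so that the angle at H is exactly 105 deg
    direction = -np.cos(np.radians(105.0)) * u + np.sin(np.radians(105.0)) * perp
    target = h8 + 2.3 * direction
    d_a = np.linalg.norm(target - c8)
    assert d_a < DEFAULT_PARAMS.vdw("C") + DEFAULT_PARAMS.vdw("O") + 1.0
    b1, b2 = _translated_copy(inst, target - inst.xyz(6))  # move O6 there
    assert all((hb.d_atom, hb.a_atom) != (8, 6) for hb in detect_hbonds(b1, b2))


def test_out_of_plane_contact_rejected():
    inst = ideal_base("A", "R", "1H 3 7 9R")
    n1, n7 = inst.xyz(1), inst.xyz(7)
    target = n1 + np.array([0.0, 0.0, 2.9])  # straight above the plane
    b1, b2 = _translated_copy(inst, target - n7)
    assert all((hb.d_atom, hb.a_atom) != (1, 7) for hb in detect_hbonds(b1, b2))


def test_brute_force_oracle_equivalence(catalog_by_name):
    """detect_hbonds agrees with a naive enumeration applying the same
    distance / plane / angle tests and the same atom-exclusive assignment."""
    p = DEFAULT_PARAMS
    for text in ("AA_fWH_(16)(67)", "GG_fWH_(26)(17)(68)", "UU_fWH_(34)(45)",
                 "CC_mWW_(24)(33)(42)", "TT_mSS_(12)(21)"):
        s = catalog_by_name[text].structure
        b1, b2 = find_bases(s)
        planes = {id(b): base_plane(b) for b in (b1, b2)}
        cands = []
        for donor, acceptor in ((b1, b2), (b2, b1)):
            r_d = donor_acceptor_roles(donor.protonation, donor.code)
            r_a = donor_acceptor_roles(acceptor.protonation, acceptor.code)
            for nd, rd in r_d.items():
                if "donor" not in rd:
                    continue
                for na, ra in r_a.items():
                    if "acceptor" not in ra:
                        continue
                    d, a = donor.xyz(nd), acceptor.xyz(na)
                    v = a - d
                    dist = np.linalg.norm(v)
                    d_el = donor.template.interaction_element(nd)
                    a_el = acceptor.template.interaction_element(na)
                    if dist > p.vdw(d_el) + p.vdw(a_el) + p.da_margin:
                        continue
                    angs = []
                    for b in (b1, b2):
                        nrm = planes[id(b)][1]
                        angs.append(np.degrees(np.arcsin(abs(np.dot(v, nrm)) / dist)))
                    if max(angs) >= p.plane_angle_max:
                        continue
                    hs = donor.attached_h(nd)
                    dha = None
                    if hs:
                        dha = max(
                            np.degrees(
                                np.arccos(
                                    np.clip(
                                        np.dot(
                                            _unit(d - donor.structure.atoms[h].xyz),
                                            _unit(a - donor.structure.atoms[h].xyz),
                                        ),
                                        -1,
                                        1,
                                    )
                                )
                            )
                            for h in hs
                        )
                        if dha < p.dha_min:
                            continue
                    slack = dist - (p.vdw(d_el) + p.vdw(a_el))
                    cands.append((slack, id(donor), nd, id(acceptor), na))
        cands.sort()
        used, expected = set(), set()
        for slack, did, nd, aid, na in cands:
            if (did, nd) in used or (aid, na) in used:
                continue
            used |= {(did, nd), (aid, na)}
            expected.add((did, nd, aid, na))
        got = {
            (id(hb.donor_base), hb.d_atom, id(hb.acceptor_base), hb.a_atom)
            for hb in detect_hbonds(b1, b2)
        }
        assert got == expected, text


# ---------------------------------------------------------------------------
# pairs


def test_two_bases_sharing_one_bond_make_no_pair(catalog_by_name):
    """Removing one N3-H from a two-bond uracil pair leaves a single
    hydrogen bond, which is below the pair threshold."""
    src = catalog_by_name["UU_mWW_(34)(43)"].structure
    s = CrystalStructure(src.id, None, [a.copy() for a in src.atoms])
    infer_bonds(s)
    b1, _ = find_bases(s)
    drop = b1.attached_h(3)[0]
    s2 = CrystalStructure(src.id, None,
                          [a.copy() for i, a in enumerate(s.atoms) if i != drop])
    infer_bonds(s2)
    b1, b2 = find_bases(s2)
    assert len(detect_hbonds(b1, b2)) == 1
    assert detect_pairs(s2) == []


def test_symmetric_fixture_bond_geometries_match(catalog_by_name):
    for text in ("AA_mWW_(16)(61)", "AA_mSS_(23)(32)", "UU_mWW_(34)(43)"):
        pr = detect_pairs(catalog_by_name[text].structure)[0]
        assert len(pr.hbonds) == 2
        d1, d2 = (hb.d_a for hb in pr.hbonds)
        assert d1 == pytest.approx(d2, abs=1e-6)


def test_threshold_monotonicity(catalog_by_name):
    """Tightening the distance margin or the plane angle never adds pairs."""
    for text in ("AA_fWH_(16)(67)", "HxHx_fWH_(17)(26)"):
        s = catalog_by_name[text].structure
        base = len(detect_pairs(s, DEFAULT_PARAMS))
        tighter = len(detect_pairs(s, DEFAULT_PARAMS.copy(da_margin=0.0)))
        flatter = len(detect_pairs(s, DEFAULT_PARAMS.copy(plane_angle_max=20.0)))
        much_tighter = len(detect_pairs(s, DEFAULT_PARAMS.copy(da_margin=-1.0)))
        assert tighter <= base and flatter <= base
        assert much_tighter <= tighter


def test_pair_geometry_c1_c1(catalog_by_name):
    substituted = detect_pairs(catalog_by_name["TT_mWW_(34)(43)"].structure)[0]
    geo = pair_geometry(substituted)
    assert geo["c1_c1"] is not None and geo["c1_c1"] > 5.0
    free = detect_pairs(catalog_by_name["AA_mSS_(39)(93)"].structure)[0]
    assert pair_geometry(free)["c1_c1"] is None


def test_inversion_wrapped_pair_deduplicated():
    """P-1 crystal with half a pair in the asymmetric unit: the detector must
    report exactly one symmetry-generated pair."""
    inst = ideal_base("U", "R", "1R 3H")
    n3, o4 = inst.xyz(3), inst.xyz(4)
    centre = 0.5 * (n3 + o4) + 1.45 * _unit(0.5 * (n3 + o4) - inst.ring_xyz().mean(axis=0))
    cell = UnitCell(25.0, 25.0, 25.0, 90, 90, 90, symops=["x,y,z", "-x,-y,-z"])
    atoms = []
    for a in inst.structure.atoms:
        na = a.copy()
        na.xyz = a.xyz - centre
        na.frac = cell.fractionalize(na.xyz)
        atoms.append(na)
    s = CrystalStructure("pminus1", cell, atoms, bonds=list(inst.structure.bonds))
    pairs = detect_pairs(s)
    assert len(pairs) == 1
    assert pairs[0].name == "UU_mWW_(34)(43)"
    assert pairs[0].symmetry_generated


# ---------------------------------------------------------------------------
# D-H normalization


def _shrunk_nh_pair(catalog_by_name, factor=0.86 / 1.009):
    src = catalog_by_name["UU_mWW_(34)(43)"].structure
    s = CrystalStructure(src.id, None, [a.copy() for a in src.atoms], list(src.bonds))
    nbrs = s.neighbor_map()
    for i, a in enumerate(s.atoms):
        if a.element != "H":
            continue
        (j,) = nbrs[i]
        if s.atoms[j].element == "N":
            a.xyz = s.atoms[j].xyz + (a.xyz - s.atoms[j].xyz) * factor
    return s


def test_normalize_dh_extends_xray_hydrogens(catalog_by_name):
    s = _shrunk_nh_pair(catalog_by_name)
    pr = detect_pairs(s)[0]
    for hb in pr.hbonds:
        assert hb.d_h == pytest.approx(0.86, abs=1e-6)
        nb = normalize_dh(hb)
        assert nb.d_h == pytest.approx(1.009, abs=1e-9)
        assert nb.d_a == pytest.approx(hb.d_a, abs=1e-12)  # D...A untouched
        # H moved along the bond: recomputed H...A consistent with geometry
        assert nb.h_a < hb.h_a
        again = normalize_dh(nb)
        assert again.d_h == pytest.approx(nb.d_h, abs=1e-6)
        assert again.dha == pytest.approx(nb.dha, abs=1e-6)


def test_normalize_dh_preserves_collinearity():
    inst = ideal_base("A", "R", "1H 3 7 9R")
    n1 = inst.xyz(1)
    h = inst.structure.atoms[inst.attached_h(1)[0]].xyz
    # exact linear D-H...A
    target = n1 + _unit(h - n1) * 2.9
    b1, b2 = _translated_copy(inst, target - inst.xyz(7))
    hb = next(h_ for h_ in detect_hbonds(b1, b2) if (h_.d_atom, h_.a_atom) == (1, 7))
    assert hb.dha == pytest.approx(180.0, abs=1e-6)
    nb = normalize_dh(hb)
    assert nb.dha == pytest.approx(180.0, abs=1e-6)


def test_normalize_dh_without_hydrogen_is_noop(catalog_by_name):
    src = catalog_by_name["UU_mWW_(34)(43)"].structure
    s = CrystalStructure(src.id, None,
                         [a.copy() for a in src.atoms if a.element != "H"])
    infer_bonds(s)
    pr = detect_pairs(s)[0]
    for hb in pr.hbonds:
        nb = normalize_dh(hb)
        assert nb.h_xyz is None and nb.d_h is None and nb.dha is None


# ---------------------------------------------------------------------------
# invariances


def test_rigid_motion_invariance(catalog_by_name):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(7)
    for text in ("AA_fWH_(16)(67)", "CC_mWW_(24)(33)(42)"):
        src = catalog_by_name[text].structure
        ref = detect_pairs(src)[0]
        ref_das = sorted(round(hb.d_a, 6) for hb in ref.hbonds)
        for _ in range(5):
            rot = Rotation.random(random_state=rng)
            shift = rng.normal(0, 20, 3)
            moved = CrystalStructure(src.id, None, [a.copy() for a in src.atoms],
                                     list(src.bonds))
            for a in moved.atoms:
                a.xyz = rot.apply(a.xyz) + shift
            pr = detect_pairs(moved)[0]
            assert pr.name == ref.name
            assert sorted(round(hb.d_a, 6) for hb in pr.hbonds) == ref_das
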