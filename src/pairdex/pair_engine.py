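"""Detection of planar, doubly hydrogen-bonded base pairs and their geometry.

A candidate donor...acceptor contact becomes a hydrogen bond when (i) the
donor/acceptor roles are compatible with the observed protonation (or with
any chemically possible protonation when hydrogens were not determined),
(ii) the D...A distance is within the Bondi vdW-radius sum + 1 A, (iii) the
D...A vector lies within 45 deg of both nucleobase ring planes, and (iv)
when a hydrogen is modeled on the donor, the D-H...A angle reaches 120 deg.
Two or more such bonds make a base pair.  X-ray D-H bond lengths are
renormalized to mean neutron values before geometry is reported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .base_recognition import BaseInstance, find_bases
from .chem_templates import DEFAULT_PARAMS, GeometryParams, donor_acceptor_roles
from .errors import DegenerateGeometryError
from .structure_io import CrystalStructure, expand_symmetry, infer_bonds


@dataclass
class HBond:
    donor_base: BaseInstance
    acceptor_base: BaseInstance
    d_atom: int          # canonical number on the donor base
    a_atom: int          # canonical number on the acceptor base
    d_a: float
    bond_class: str      # e.g. "NH...O"
    plane_angles: tuple[float, float]
    h_atom: int | None = None
    h_xyz: np.ndarray | None = None
    d_h: float | None = None
    h_a: float | None = None
    dha: float | None = None
    normalized: bool = False


@dataclass
class BasePair:
    base1: BaseInstance
    base2: BaseInstance
    hbonds: list[HBond]
    interplanar_angle: float
    c1_c1: float | None
    name: str | None = None
    symmetry_generated: bool = False


def base_plane(b: BaseInstance) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares ring plane with a face-labelled normal.

    The normal's sign follows the right-hand rule around the canonical
    N1 -> C2 -> ... -> C6 ring circuit, so parallel normals mean the two
    bases expose the same face ("m" orientation) and antiparallel normals
    the opposite faces ("f").
    """
    pts = b.ring_xyz()
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-6:
        raise DegenerateGeometryError(f"{b.code}: ring atoms are collinear")
    normal = vt[2]
    newell = np.zeros(3)
    for i in range(len(pts)):
        p, q = centered[i], centered[(i + 1) % len(pts)]
        newell += np.cross(p, q)
    if np.dot(normal, newell) < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def _angle_to_plane(v: np.ndarray, normal: np.ndarray) -> float:
    """Angle (deg) between a vector and a plane with the given unit normal."""
    s = abs(float(np.dot(v, normal))) / np.linalg.norm(v)
    return float(np.degrees(np.arcsin(min(1.0, s))))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle (deg) at vertex b."""
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(b1: BaseInstance, b2: BaseInstance,
                  p: GeometryParams = DEFAULT_PARAMS) -> list[HBond]:
    """Hydrogen bonds between two base instances under the survey criteria.

    All passing donor/acceptor contacts are collected first; each canonical
    atom then participates in at most one bond of the pair, the contact
    with the most slack below its vdW-sum threshold winning.  This keeps
    the defining bonds of a pair type and discards weaker secondary
    contacts that merely ride along on already-engaged atoms.
    """
    roles1 = donor_acceptor_roles(b1.protonation, b1.code)
    roles2 = donor_acceptor_roles(b2.protonation, b2.code)
    plane1, plane2 = base_plane(b1), base_plane(b2)
    candidates: list[tuple[tuple, HBond]] = []
    seen: set[tuple] = set()
    for donor, d_roles, acceptor, a_roles, key in (
        (b1, roles1, b2, roles2, "12"),
        (b2, roles2, b1, roles1, "21"),
    ):
        for nd, rd in d_roles.items():
            if "donor" not in rd:
                continue
            for na, ra in a_roles.items():
                if "acceptor" not in ra:
                    continue
                sig = (key, nd, na)
                alt = ("21" if key == "12" else "12", na, nd)
                if sig in seen or alt in seen:
                    continue
                hb = _try_bond(donor, nd, acceptor, na, plane1, plane2, p)
                if hb is not None:
                    seen.add(sig)
                    d_el = donor.template.interaction_element(nd)
                    a_el = acceptor.template.interaction_element(na)
                    slack = hb.d_a - (p.vdw(d_el) + p.vdw(a_el))
                    order = (slack, -(hb.dha or 0.0), nd, na, key)
                    candidates.append((order, hb))
    candidates.sort(key=lambda t: t[0])
    bonds: list[HBond] = []
    used: set[tuple[int, int]] = set()  # (base-id, canonical atom)
    for _, hb in candidates:
        kd = (id(hb.donor_base), hb.d_atom)
        ka = (id(hb.acceptor_base), hb.a_atom)
        if kd in used or ka in used:
            continue
        used.add(kd)
        used.add(ka)
        bonds.append(hb)
    return bonds


def _try_bond(donor, nd, acceptor, na, plane1, plane2, p: GeometryParams) -> HBond | None:
    d_xyz, a_xyz = donor.xyz(nd), acceptor.xyz(na)
    d_el = donor.template.interaction_element(nd)
    a_el = acceptor.template.interaction_element(na)
    v = a_xyz - d_xyz
    d_a = float(np.linalg.norm(v))
    if d_a < 0.5 or d_a > p.vdw(d_el) + p.vdw(a_el) + p.da_margin:
        return None
    angles = (_angle_to_plane(v, plane1[1]), _angle_to_plane(v, plane2[1]))
    if max(angles) >= p.plane_angle_max:
        return None
    hb = HBond(
        donor_base=donor,
        acceptor_base=acceptor,
        d_atom=nd,
        a_atom=na,
        d_a=d_a,
        bond_class=f"{d_el}H...{a_el}",
        plane_angles=angles,
    )
    h_candidates = donor.attached_h(nd)
    if h_candidates:
        structure = donor.structure
        best, best_dha = None, -1.0
        for h in h_candidates:
            dha = _angle(d_xyz, structure.atoms[h].xyz, a_xyz)
            if dha > best_dha:
                best, best_dha = h, dha
        if best_dha < p.dha_min:
            return None
        h_xyz = structure.atoms[best].xyz
        hb.h_atom = best
        hb.h_xyz = h_xyz.copy()
        hb.d_h = float(np.linalg.norm(h_xyz - d_xyz))
        hb.h_a = float(np.linalg.norm(a_xyz - h_xyz))
        hb.dha = best_dha
    return hb


def normalize_dh(hb: HBond, p: GeometryParams = DEFAULT_PARAMS) -> HBond:
    """Extend the D-H bond to its mean neutron length; D...A is untouched."""
    if hb.h_xyz is None:
        return dataclasses.replace(hb)
    d_xyz = hb.donor_base.xyz(hb.d_atom)
    a_xyz = hb.acceptor_base.xyz(hb.a_atom)
    d_el = hb.donor_base.template.interaction_element(hb.d_atom)
    target = p.neutron_dh.get(d_el)
    if target is None:
        return dataclasses.replace(hb)
    direction = hb.h_xyz - d_xyz
    direction = direction / np.linalg.norm(direction)
    new_h = d_xyz + direction * target
    return dataclasses.replace(
        hb,
        h_xyz=new_h,
        d_h=float(target),
        h_a=float(np.linalg.norm(a_xyz - new_h)),
        dha=_angle(d_xyz, new_h, a_xyz),
        normalized=True,
    )


def interplanar_angle(b1: BaseInstance, b2: BaseInstance) -> float:
    n1, n2 = base_plane(b1)[1], base_plane(b2)[1]
    ang = float(np.degrees(np.arccos(np.clip(abs(float(np.dot(n1, n2))), 0.0, 1.0))))
    return ang


def _make_pair(b1: BaseInstance, b2: BaseInstance, hbonds: list[HBond]) -> BasePair:
    c1_c1 = None
    if b1.c1_atom is not None and b2.c1_atom is not None:
        c1_c1 = float(
            np.linalg.norm(
                b1.structure.atoms[b1.c1_atom].xyz - b2.structure.atoms[b2.c1_atom].xyz
            )
        )
    return BasePair(
        base1=b1,
        base2=b2,
        hbonds=hbonds,
        interplanar_angle=interplanar_angle(b1, b2),
        c1_c1=c1_c1,
        symmetry_generated=b1.is_symmetry_mate or b2.is_symmetry_mate,
    )


def detect_pairs(s: CrystalStructure, p: GeometryParams = DEFAULT_PARAMS,
                 expand: bool = True) -> list[BasePair]:
    """All base pairs in *s*, symmetry-expanded and deduplicated.

    When the structure has a cell, symmetry mates within the contact
    envelope are generated first; pairs that are symmetry images of one
    another are collapsed through a canonical signature (pair name + sorted
    quantized bond distances + quantized interplanar angle and C1'...C1').
    """
    from .nomenclature import canonical_name  # deferred: nomenclature imports our types

    if not s.bonds and s.atoms:
        infer_bonds(s, params=p)
    if expand and s.cell is not None and len(s.cell.symops) > 0:
        expand_symmetry(s, params=p)
    bases = find_bases(s)
    pairs: list[BasePair] = []
    seen: set[tuple] = set()
    for i in range(len(bases)):
        for j in range(i + 1, len(bases)):
            b1, b2 = bases[i], bases[j]
            if b1.is_symmetry_mate and b2.is_symmetry_mate:
                continue  # images of an asymmetric-unit pair
            hbonds = detect_hbonds(b1, b2, p)
            if len(hbonds) < p.min_hbonds:
                continue
            pair = _make_pair(b1, b2, hbonds)
            try:
                pair.name = canonical_name(pair).text
                name_key = pair.name
            except Exception:
                name_key = f"{b1.code}{b2.code}:" + ",".join(
                    sorted(f"{hb.d_atom}{hb.a_atom}" for hb in hbonds)
                )
            sig = (
                name_key,
                tuple(sorted(round(hb.d_a, 2) for hb in hbonds)),
                round(pair.interplanar_angle, 0),
                None if pair.c1_c1 is None else round(pair.c1_c1, 2),
            )
            if sig in seen:
                continue
            seen.add(sig)
            pairs.append(pair)
    return pairs


def pair_geometry(pr: BasePair, p: GeometryParams = DEFAULT_PARAMS) -> dict:
    """Normalized geometry record for one pair."""
    bonds = []
    for hb in pr.hbonds:
        nb = normalize_dh(hb, p)
        bonds.append(
            {
                "class": nb.bond_class,
                "d_atom": nb.d_atom,
                "a_atom": nb.a_atom,
                "d_a": nb.d_a,
                "d_h": nb.d_h,
                "h_a": nb.h_a,
                "dha": nb.dha,
            }
        )
    return {
        "bonds": bonds,
        "interplanar_angle": pr.interplanar_angle,
        "c1_c1": pr.c1_c1,
    }
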