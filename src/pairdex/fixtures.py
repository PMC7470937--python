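"""Synthetic idealized nucleobases and constructed base-pair structures.

Every pair type of the homo-pair catalog can be realized as a small
coordinate-only structure: planar bases with frozen ideal internal
geometry, hydrogens placed according to an observed protonation pattern,
and the second base positioned by a rigid in-plane fit so each named
donor/acceptor contact sits at its target distance (2.9 A for N/O donors,
3.4 A for carbon donors, matching the survey's observed ranges).  The
generator is the package's test substrate: detection, naming, protonation
and charge classification must all round-trip on its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .base_recognition import BaseInstance, find_bases
from .chem_templates import (
    DEFAULT_PARAMS,
    GeometryParams,
    donor_acceptor_roles,
    get_template,
    parse_pattern,
)
from .errors import ConstructionError, SpecError
from .nomenclature import CATALOG_NAMES, PairName, parse_name
from .structure_io import Atom, CrystalStructure, infer_bonds

N_H = 1.009
C_H = 1.083
TARGET_DA_NO = 2.9   # N/O donor target D...A (A)
TARGET_DA_C = 3.4    # C donor target, middle of the observed 3.3-3.9 A range
CLASH_MIN = 2.4      # minimal allowed nonbonded heavy-heavy distance (A)

#: protonation patterns (base1, base2) realized for each catalog pair type,
#: chosen from the observed columns of the survey's per-base count tables.
CATALOG_PATTERNS: dict[str, tuple[str, str]] = {
    "AA_mWW_(12)(21)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fWW_(16)(21)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_mWW_(16)(61)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fWH_(18)(27)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fWH_(16)(67)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fWS_(19)(63)": ("1H 3 7H 9", "1H 3 7H 9"),
    "AA_mHH_(67)(76)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fHH_(67)(78)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_mHH_(78)(87)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fHS_(63)(72)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_mHS_(63)(79)": ("1H 3 7 9H", "1H 3 7 9H"),
    "AA_mHS_(72)(83)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_fHS_(79)(83)": ("1H 3 7 9H", "1H 3 7 9H"),
    "AA_mSS_(23)(32)": ("1 3 7 9R", "1 3 7 9R"),
    "AA_mSS_(39)(93)": ("1 3 7 9H", "1 3 7 9H"),
    "GG_mWW_(16)(61)": ("1H 3 7 9R", "1H 3 7 9R"),
    "GG_mWH_(16)(27)": ("1H 3 7 9R", "1H 3 7 9R"),
    "GG_fWH_(16)(67)": ("1H 3 7 9R", "1H 3 7H 9R"),
    "GG_fWH_(26)(17)(68)": ("1H 3 7 9R", "1H 3 7 9R"),
    "GG_mHH_(67)(76)": ("1H 3 7H 9H", "1H 3 7H 9H"),
    "GG_mSS_(23)(32)": ("1H 3 7 9R", "1H 3 7 9R"),
    "GG_mSS_(39)(93)": ("1H 3 7 9H", "1H 3 7 9H"),
    "HxHx_mWW_(16)(61)": ("1H 3 7 9H", "1H 3 7 9H"),
    "HxHx_fWH_(17)(26)": ("1H 3 7 9R", "1H 3 7 9R"),
    "HxHx_fWS_(13)(62)": ("1H 3 7 9R", "1H 3 7 9R"),
    "HxHx_fHS_(68)(79)": ("1H 3 7 9H", "1H 3 7 9H"),
    "HxHx_mSS_(23)(32)": ("1H 3 7 9R", "1H 3 7 9R"),
    "TT_mWW_(23)(32)": ("1R 3H", "1R 3H"),
    "TT_fWW_(23)(34)": ("1R 3H", "1R 3H"),
    "TT_mWW_(34)(43)": ("1R 3H", "1R 3H"),
    "TT_fWH_(34)(45)": ("1R 3H", "1R 3H"),
    "TT_fWS_(21)(32)": ("1H 3H", "1H 3H"),
    "TT_mSS_(12)(21)": ("1H 3H", "1H 3H"),
    "UU_mWW_(23)(32)": ("1R 3H", "1R 3H"),
    "UU_fWW_(23)(34)": ("1R 3H", "1R 3H"),
    "UU_mWW_(34)(43)": ("1R 3H", "1R 3H"),
    "UU_fWH_(34)(45)": ("1R 3H", "1R 3H"),
    "UU_mHH_(45)(54)": ("1R 3H", "1R 3H"),
    "UU_fHS_(41)(52)": ("1H 3H", "1H 3H"),
    "UU_mSS_(12)(21)": ("1H 3H", "1H 3H"),
    "CC_mWW_(23)(32)": ("1R 3H", "1R 3H"),
    "CC_mWW_(24)(33)(42)": ("1R 3", "1R 3H"),
    "CC_mWW_(34)(43)": ("1R 3", "1R 3"),
    "CC_fWH_(24)(35)": ("1R 3", "1R 3"),
    "CC_mWH_(25)(34)": ("1R 3", "1R 3H"),
    "CC_fWS_(26)(31)(42)": ("1H 3", "1H 3"),
    "CC_mSS_(12)(21)": ("1H 3H", "1H 3H"),
}


@dataclass
class PairSpec:
    """Recipe for one synthetic pair structure."""

    name: PairName
    protonation: tuple[str, str]
    target_da: float | None = None  # override for every bond; default by donor element
    noise_sigma: float = 0.0
    tilt: float = 0.0
    seed: int = 0


@dataclass
class FixtureEntry:
    spec: PairSpec
    structure: CrystalStructure
    expected: PairName


# ---------------------------------------------------------------------------
# single ideal base


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _base_coords(code: str, substitution: str, protonation: str) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, xyz) for one planar base; z = 0 for heavy atoms."""
    t = get_template(code)
    sub, protonated = parse_pattern(protonation, code)
    if sub != substitution:
        raise SpecError(
            f"pattern {protonation!r} implies substitution {sub!r}, requested {substitution!r}"
        )
    pos = {name: np.array([x, y, 0.0]) for name, (x, y) in t.coords.items()}
    ring = dict(t.ring_atoms)
    exo = t.exocyclic_by_position

    atoms: list[tuple[str, str, np.ndarray]] = []
    for n, el in t.ring_atoms:
        atoms.append((f"{el}{n}", el, pos[f"{el}{n}"]))
    for n, el, kind in t.exocyclic_atoms:
        name = f"{el}{7 if kind == 'methyl' else n}"
        atoms.append((name, el, pos[name]))
    if substitution == "R":
        pos["C1S"] = pos["c1p"]
        atoms.append(("C1S", "C", pos["C1S"]))

    if protonated is None:
        return atoms  # undetermined hydrogens: none placed at all

    ring_order = [f"{el}{n}" for n, el in t.ring_atoms]
    nbrs: dict[str, list[str]] = {nm: [] for nm in pos}
    for a, b in t.bonds:
        na, nb = f"{ring[a]}{a}", f"{ring[b]}{b}"
        nbrs[na].append(nb)
        nbrs[nb].append(na)
    for n, el, kind in t.exocyclic_atoms:
        name = f"{el}{7 if kind == 'methyl' else n}"
        nbrs[name].append(f"{ring[n]}{n}")
        nbrs[f"{ring[n]}{n}"].append(name)

    def bisector_h(name: str, length: float) -> np.ndarray:
        x = pos[name]
        d = -sum(_unit(pos[nb] - x) for nb in nbrs[name])
        return x + _unit(d) * length

    def methyl_hs(cname: str, anchor: str) -> list[np.ndarray]:
        c = pos[cname]
        u = _unit(c - pos[anchor])
        p = _unit(np.cross(np.array([0.0, 0.0, 1.0]), u))
        w = np.array([0.0, 0.0, 1.0])
        out = []
        for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            d = u / 3.0 + np.sqrt(8.0) / 3.0 * (np.cos(phi) * p + np.sin(phi) * w)
            out.append(c + _unit(d) * C_H)
        return out

    h_index = 0

    def add_h(xyz: np.ndarray):
        nonlocal h_index
        h_index += 1
        atoms.append((f"H{h_index}", "H", xyz))

    for n in t.ring_n_positions:
        if substitution == "R" and n == t.glycosidic_atom:
            continue
        if n in protonated:
            add_h(bisector_h(f"N{n}", N_H))
    for n, el, kind in t.exocyclic_atoms:
        if kind == "amino":
            x = pos[f"{el}{n}"]
            u = _unit(x - pos[f"{ring[n]}{n}"])
            # sp2 amino: H-N-C angles of 120 deg put each N-H vector 60 deg
            # off the C->N extension
            for ang in (np.pi / 3, -np.pi / 3):
                c, s = np.cos(ang), np.sin(ang)
                d = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1], 0.0])
                add_h(x + d * N_H)
        elif kind == "methyl":
            for h in methyl_hs("C7", f"{ring[n]}{n}"):
                add_h(h)
    # ring C-H
    for n, el in t.ring_atoms:
        if el != "C" or n in exo:
            continue
        if t.kind == "purine" and n in (4, 5):
            continue
        add_h(bisector_h(f"C{n}", C_H))
    if substitution == "R":
        for h in methyl_hs("C1S", f"N{t.glycosidic_atom}"):
            add_h(h)
    return atoms


def ideal_base(code: str, substitution: str, protonation: str,
               structure_id: str = "ideal") -> BaseInstance:
    """A recognized :class:`BaseInstance` built from ideal coordinates."""
    atoms = _base_coords(code, substitution, protonation)
    s = CrystalStructure(
        id=structure_id,
        cell=None,
        atoms=[Atom(nm, el, xyz.copy()) for nm, el, xyz in atoms],
    )
    infer_bonds(s)
    found = find_bases(s)
    if len(found) != 1:
        raise SpecError(f"ideal {code} base not uniquely recognized ({len(found)} matches)")
    return found[0]


# ---------------------------------------------------------------------------
# pair construction


def _bond_assignments(name: PairName, patterns: tuple[str, str]):
    """Resolve donor direction and target distance for every named bond."""
    roles = [
        donor_acceptor_roles(patterns[0], name.codes[0]),
        donor_acceptor_roles(patterns[1], name.codes[1]),
    ]
    out = []
    for n1, n2 in name.bonds:
        r1, r2 = roles[0].get(n1, frozenset()), roles[1].get(n2, frozenset())
        if "donor" in r1 and "acceptor" in r2:
            donor_side = 0
        elif "donor" in r2 and "acceptor" in r1:
            donor_side = 1
        else:
            raise SpecError(
                f"bond ({n1}{n2}) of {name.text} impossible under patterns {patterns}"
            )
        d_code = name.codes[donor_side]
        d_atom = n1 if donor_side == 0 else n2
        d_el = get_template(d_code).interaction_element(d_atom)
        out.append((n1, n2, donor_side, d_el))
    return out


def build_pair(spec: PairSpec, params: GeometryParams = DEFAULT_PARAMS) -> CrystalStructure:
    """Construct a two-base structure realizing *spec*.

    Base 1 lies in the z = 0 plane; base 2 is flipped for "f" orientation
    and then rigidly placed in-plane so every named donor/acceptor pair
    sits at its target distance, with soft preferences for near-linear
    D-H...A geometry, absence of steric clash, and no incidental contacts
    that would qualify as extra hydrogen bonds.
    """
    name = spec.name
    t1, t2 = get_template(name.codes[0]), get_template(name.codes[1])
    sub1 = parse_pattern(spec.protonation[0], name.codes[0])[0]
    sub2 = parse_pattern(spec.protonation[1], name.codes[1])[0]
    atoms1 = _base_coords(name.codes[0], sub1, spec.protonation[0])
    atoms2 = _base_coords(name.codes[1], sub2, spec.protonation[1])
    assignments = _bond_assignments(name, spec.protonation)

    lookup1 = {nm: xyz for nm, _, xyz in atoms1}
    xyz2 = np.array([xyz for _, _, xyz in atoms2])
    names2 = [nm for nm, _, _ in atoms2]
    if name.orientation == "f":
        xyz2 = xyz2 * np.array([1.0, -1.0, -1.0])
    idx2 = {nm: i for i, nm in enumerate(names2)}

    heavy1 = np.array([xyz for nm, el, xyz in atoms1 if el != "H"])
    heavy2_idx = [i for i, (nm, el, _) in enumerate(atoms2) if el != "H"]

    # specified bonds: anchor points, targets, donor-H bookkeeping
    bonds = []
    for (n1, n2, donor_side, d_el) in assignments:
        target = spec.target_da if spec.target_da is not None else (
            TARGET_DA_C if d_el == "C" else TARGET_DA_NO
        )
        a1_name = t1.interaction_atom(n1)
        a2_name = t2.interaction_atom(n2)
        bonds.append((lookup1[a1_name], idx2[a2_name], donor_side, target, a1_name, a2_name))

    # hydrogens attached to each donor (for the linearity preference)
    donor_hs = []
    for (n1, n2, donor_side, d_el), (p1, i2, _, target, a1n, a2n) in zip(assignments, bonds):
        if donor_side == 0:
            dn = t1.interaction_atom(n1)
            hs = [xyz for nm, el, xyz in atoms1 if el == "H" and np.linalg.norm(xyz - lookup1[dn]) < 1.25]
            donor_hs.append(("1", lookup1[dn], hs, i2))
        else:
            dn = t2.interaction_atom(n2)
            hs = [idx2[nm] for nm, el, _ in atoms2 if el == "H" and np.linalg.norm(xyz2[idx2[nm]] - xyz2[idx2[dn]]) < 1.25]
            donor_hs.append(("2", idx2[dn], hs, p1))

    named = {(n1, n2) for n1, n2, _, _ in assignments}

    def transform(v, theta, tx, ty):
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return v @ rot.T + np.array([tx, ty, 0.0])

    extra_penalties: list[tuple[np.ndarray, int, float]] = []

    def objective(x):
        theta, tx, ty = x
        moved = transform(xyz2, theta, tx, ty)
        val = 0.0
        for p1, i2, _, target, _, _ in bonds:
            val += (np.linalg.norm(p1 - moved[i2]) - target) ** 2
        # near-linear D-H...A preference
        for side, d, hs, other in donor_hs:
            if not hs:
                continue
            if side == "1":
                d_xyz, a_xyz = d, moved[other]
                h_xyzs = hs
            else:
                d_xyz, a_xyz = moved[d], other
                h_xyzs = [moved[h] for h in hs]
            v = _unit(a_xyz - d_xyz)
            best = max(float(np.dot(_unit(h - d_xyz), v)) for h in h_xyzs)
            val += 1.0 * (1.0 - best) ** 2
        # steric clash
        mh = moved[heavy2_idx]
        dm = cdist(heavy1, mh)
        val += 10.0 * float(np.sum(np.clip(CLASH_MIN + 0.05 - dm, 0.0, None) ** 2))
        # targeted exclusion of contacts that detected as unwanted extra bonds
        for p1, i2, limit in extra_penalties:
            d = np.linalg.norm(p1 - moved[i2])
            val += 2.0 * max(0.0, limit - d) ** 2
        return val

    def _feasible(x):
        moved = transform(xyz2, *x)
        residuals = [abs(np.linalg.norm(p1 - moved[i2]) - target)
                     for p1, i2, _, target, _, _ in bonds]
        clash = float(cdist(heavy1, moved[heavy2_idx]).min())
        return clash >= CLASH_MIN - 1e-6 and (
            max(residuals) < 0.05 or (len(bonds) > 2 and max(residuals) < 0.45)
        )

    # anchor bonds used for the exact two-circle placement at fixed rotation
    pa, ia, _, da_, _, _ = bonds[0]
    pb, ib, _, db_, _, _ = bonds[-1]

    def _exact_translations(theta):
        c, s_ = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s_], [s_, c]])
        c1 = pa[:2] - rot @ xyz2[ia][:2]
        c2 = pb[:2] - rot @ xyz2[ib][:2]
        d = float(np.linalg.norm(c2 - c1))
        if d < 1e-6:
            # concentric circles: for symmetric pairs at theta = pi the
            # whole circle of translations keeps both bonds exact
            if abs(da_ - db_) > 1e-6:
                return []
            phis = np.linspace(0.0, 2 * np.pi, 180, endpoint=False)
            return [c1 + da_ * np.array([np.cos(p), np.sin(p)]) for p in phis]
        if d > da_ + db_ or d < abs(da_ - db_):
            return []
        a = (d * d + da_ * da_ - db_ * db_) / (2 * d)
        h2 = da_ * da_ - a * a
        if h2 < 0:
            return []
        h = np.sqrt(max(0.0, h2))
        u = (c2 - c1) / d
        perp = np.array([-u[1], u[0]])
        base = c1 + a * u
        return [base + h * perp, base - h * perp]

    def solve(extra_starts=()):
        # deterministic scan of the distance-exact solution family
        best = None
        for theta in np.linspace(0.0, 2 * np.pi, 720, endpoint=False):
            for txy in _exact_translations(theta):
                x = (theta, txy[0], txy[1])
                if not _feasible(x):
                    continue
                f = objective(x)
                if best is None or f < best[0]:
                    best = (f, np.array(x))
        starts = [best[1]] if best is not None else []
        starts.extend(extra_starts)
        for x0 in starts:
            res = minimize(objective, x0, method="Powell",
                           options={"xtol": 1e-7, "ftol": 1e-11, "maxiter": 3000})
            if _feasible(res.x) and (best is None or res.fun < best[0]):
                best = (res.fun, res.x)
        return best

    def assemble(x) -> CrystalStructure:
        moved = transform(xyz2, *x)
        atoms = [Atom(f"{nm}A", el, xyz.copy()) for nm, el, xyz in atoms1]
        atoms += [
            Atom(f"{names2[i]}B", atoms2[i][1], moved[i].copy())
            for i in range(len(atoms2))
        ]
        s = CrystalStructure(id=name.text, cell=None, atoms=atoms)
        infer_bonds(s, params=params)
        return s

    best = solve()
    if best is None:
        raise ConstructionError(
            f"{name.text}: could not place bases to satisfy bonds {name.bonds}"
        )
    s = assemble(best[1])

    # verify against the detector; repel incidental extra hydrogen bonds
    from .pair_engine import detect_hbonds  # deferred: pair_engine is import-light

    for _ in range(3):
        found = find_bases(s)
        if len(found) != 2:
            break
        f1, f2 = found
        detected = set()
        for hb in detect_hbonds(f1, f2, params):
            if hb.donor_base is f1:
                detected.add((hb.d_atom, hb.a_atom))
            else:
                detected.add((hb.a_atom, hb.d_atom))
        extras = detected - named
        if not extras:
            break
        for n1, n2 in extras:
            ea = t1.interaction_element(n1)
            eb = t2.interaction_element(n2)
            limit = params.vdw(ea) + params.vdw(eb) + params.da_margin + 0.05
            extra_penalties.append((lookup1[t1.interaction_atom(n1)], idx2[t2.interaction_atom(n2)], limit))
        best = solve(extra_starts=[list(best[1])])
        if best is None:
            raise ConstructionError(
                f"{name.text}: cannot avoid incidental contacts {sorted(extras)}"
            )
        s = assemble(best[1])

    if spec.noise_sigma > 0 or spec.tilt != 0:
        s = perturb(s, spec.noise_sigma, spec.tilt, seed=spec.seed)
    return s


def perturb(s: CrystalStructure, noise_sigma: float = 0.0, tilt: float = 0.0,
            seed: int = 0) -> CrystalStructure:
    """Seeded Gaussian coordinate noise plus a tilt of molecule 2.

    The tilt tips the second molecule about the in-plane axis through its
    own centroid, perpendicular to the approach direction: every
    donor...acceptor vector of the pair rotates out of the ring planes by
    roughly the tilt angle, so tilts beyond the 45 deg criterion suppress
    detection while the contact distances stay nearly unchanged.
    """
    rng = np.random.default_rng(seed)
    out = CrystalStructure(
        id=s.id, cell=s.cell, atoms=[a.copy() for a in s.atoms],
        bonds=list(s.bonds), meta=dict(s.meta),
    )
    comps = out.components()
    if tilt != 0 and len(comps) >= 2:
        c1, c2 = comps[0], comps[1]
        h1 = [i for i in c1 if out.atoms[i].element != "H"]
        h2 = [i for i in c2 if out.atoms[i].element != "H"]
        x1 = np.array([out.atoms[i].xyz for i in h1])
        x2 = np.array([out.atoms[i].xyz for i in h2])
        cen1, cen2 = x1.mean(axis=0), x2.mean(axis=0)
        _, svals, vt = np.linalg.svd(x2 - cen2)
        normal = vt[2]
        approach = cen1 - cen2
        approach = approach - np.dot(approach, normal) * normal
        axis = _unit(np.cross(normal, _unit(approach)))
        rot = Rotation.from_rotvec(np.radians(tilt) * axis)
        for k in c2:
            out.atoms[k].xyz = rot.apply(out.atoms[k].xyz - cen2) + cen2
    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=(len(out.atoms), 3))
        for a, d in zip(out.atoms, noise):
            a.xyz = a.xyz + d
    return out


def catalog(params: GeometryParams = DEFAULT_PARAMS) -> list[FixtureEntry]:
    """One constructed fixture per catalog pair type (47 entries)."""
    entries = []
    for text in CATALOG_NAMES:
        pname = parse_name(text)
        spec = PairSpec(name=pname, protonation=CATALOG_PATTERNS[text])
        entries.append(FixtureEntry(spec, build_pair(spec, params), pname))
    return entries
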