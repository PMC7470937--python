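"""Crystal-structure I/O, covalent-bond inference and symmetry expansion.

Structures come in as small-molecule CIF (cell + symmetry operators +
fractional or Cartesian atom sites, optional ``_geom_bond`` table) or as
coordinate-only PDB.  Internally everything is Cartesian Angstrom.  Symmetry
expansion generates whole-molecule copies (connected covalent components)
whose atoms fall inside a contact envelope of the asymmetric unit, the way a
crystallographic contact search does; coordinate-only structures simply skip
it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .chem_templates import DEFAULT_PARAMS, GeometryParams
from .errors import EmptyStructureError, FormatError, NoSymmetryError


@dataclass
class Atom:
    label: str
    element: str
    xyz: np.ndarray  # Cartesian Angstrom
    frac: np.ndarray | None = None
    occupancy: float = 1.0
    is_symmetry_mate: bool = False
    source_op: str | None = None

    def copy(self) -> "Atom":
        return Atom(
            self.label,
            self.element,
            self.xyz.copy(),
            None if self.frac is None else self.frac.copy(),
            self.occupancy,
            self.is_symmetry_mate,
            self.source_op,
        )


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    symops: list[str] = field(default_factory=lambda: ["x,y,z"])

    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        f = self.gemmi_cell().fractionalize(gemmi.Position(*map(float, xyz)))
        return np.array([f.x, f.y, f.z])

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        p = self.gemmi_cell().orthogonalize(gemmi.Fractional(*map(float, frac)))
        return np.array([p.x, p.y, p.z])

    @property
    def volume(self) -> float:
        return self.gemmi_cell().volume


@dataclass
class CrystalStructure:
    id: str
    cell: UnitCell | None
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def has_hydrogens(self) -> bool:
        return any(a.element in ("H", "D") for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms]).reshape(-1, 3)

    def neighbor_map(self) -> dict[int, list[int]]:
        nbrs: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def components(self) -> list[list[int]]:
        """Connected covalent components (molecules), as atom-index lists."""
        nbrs = self.neighbor_map()
        seen: set[int] = set()
        comps = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in nbrs[i]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps


def _as_number(text: str) -> float:
    """Parse a CIF numeric value, tolerating standard-uncertainty suffixes."""
    try:
        return gemmi.cif.as_number(text)
    except Exception as exc:  # pragma: no cover - gemmi is lenient
        raise FormatError(f"bad numeric CIF value {text!r}") from exc


def _element_from(symbol: str, label: str) -> str:
    sym = (symbol or "").strip("+-0123456789 ")
    if not sym:
        sym = "".join(ch for ch in label if ch.isalpha())[:2]
    el = gemmi.Element(sym)
    if el.name == "X":
        el = gemmi.Element(sym[:1])
    if el.name == "X":
        raise FormatError(f"unrecognized element for atom {label!r}")
    return "H" if el.name == "D" else el.name


def _read_cif(path: Path) -> CrystalStructure:
    try:
        doc = gemmi.cif.read_file(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse CIF {path}: {exc}") from exc
    block = doc.sole_block() if len(doc) == 1 else doc[0]

    cell = None
    if block.find_value("_cell_length_a") is not None:
        cell = UnitCell(
            *[
                _as_number(block.find_value(f"_cell_length_{k}"))
                for k in ("a", "b", "c")
            ],
            *[
                _as_number(block.find_value(f"_cell_angle_{k}"))
                for k in ("alpha", "beta", "gamma")
            ],
        )
        ops = []
        for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
            col = block.find_loop(tag)
            ops.extend(gemmi.cif.as_string(v) for v in col)
        if ops:
            cell.symops = [gemmi.Op(o).triplet() for o in ops]
        if "x,y,z" not in cell.symops:
            cell.symops.insert(0, "x,y,z")

    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "?fract_x", "?fract_y", "?fract_z",
         "?Cartn_x", "?Cartn_y", "?Cartn_z", "?occupancy", "?disorder_group"],
    )
    if len(table) == 0:
        raise EmptyStructureError(f"{path} contains no atom sites")

    raw: list[tuple[Atom, str]] = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        symbol = gemmi.cif.as_string(row[1]) if row.has(1) else ""
        if row.has(2) and row.has(3) and row.has(4):
            frac = np.array([_as_number(row[i]) for i in (2, 3, 4)])
            if cell is None:
                raise FormatError(f"{path}: fractional coordinates but no cell")
            xyz = cell.orthogonalize(frac)
        elif row.has(5) and row.has(6) and row.has(7):
            xyz = np.array([_as_number(row[i]) for i in (5, 6, 7)])
            frac = cell.fractionalize(xyz) if cell is not None else None
        else:
            raise FormatError(f"{path}: atom {label} lacks coordinates")
        occ = _as_number(row[8]) if row.has(8) else 1.0
        group = gemmi.cif.as_string(row[9]) if row.has(9) else "."
        raw.append((Atom(label, _element_from(symbol, label), xyz, frac, occ), group))

    # disorder: keep ungrouped atoms plus the highest-occupancy disorder group
    groups = {g for _, g in raw if g not in (".", "", "?")}
    keep_group = None
    if groups:
        mean_occ = {
            g: float(np.mean([a.occupancy for a, gg in raw if gg == g])) for g in groups
        }
        keep_group = max(sorted(groups), key=lambda g: mean_occ[g])
    atoms = [a for a, g in raw if g in (".", "", "?") or g == keep_group]

    bonds: list[tuple[int, int]] = []
    btable = block.find("_geom_bond_", ["atom_site_label_1", "atom_site_label_2"])
    if len(btable) > 0:
        index = {a.label: i for i, a in enumerate(atoms)}
        for row in btable:
            l1, l2 = gemmi.cif.as_string(row[0]), gemmi.cif.as_string(row[1])
            if l1 in index and l2 in index:
                bonds.append(tuple(sorted((index[l1], index[l2]))))
        bonds = sorted(set(bonds))

    meta = {}
    for tag in ("_refine_ls_R_factor_gt", "_refine_ls_R_factor_all"):
        v = block.find_value(tag)
        if v is not None:
            try:
                meta["r_factor"] = _as_number(v)
                break
            except FormatError:
                pass
    return CrystalStructure(id=path.stem, cell=cell, atoms=atoms, bonds=bonds, meta=meta)


def _read_pdb(path: Path) -> CrystalStructure:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    cell = None
    gc = st.cell
    if gc.is_crystal() and gc.volume > 1.001:  # gemmi uses a 1x1x1 dummy when CRYST1 absent
        cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
        if sg is not None:
            cell.symops = [op.triplet() for op in sg.operations()]
    atoms = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    if at.altloc not in ("", "A", "\x00"):
                        continue  # keep first alternative conformation
                    xyz = np.array([at.pos.x, at.pos.y, at.pos.z])
                    frac = cell.fractionalize(xyz) if cell is not None else None
                    atoms.append(Atom(at.name, _element_from(at.element.name, at.name), xyz, frac, at.occ))
        break  # first model only
    if not atoms:
        raise EmptyStructureError(f"{path} contains no atoms")
    return CrystalStructure(id=path.stem, cell=cell, atoms=atoms)


def read_structure(path: str | Path, format: str = "auto") -> CrystalStructure:
    """Read a CIF or PDB file into a :class:`CrystalStructure`."""
    path = Path(path)
    if format == "auto":
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "cif"
    if format == "cif":
        return _read_cif(path)
    if format == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown format {format!r}")


def infer_bonds(s: CrystalStructure, tol: float | None = None,
                params: GeometryParams = DEFAULT_PARAMS) -> CrystalStructure:
    """Fill ``s.bonds`` from interatomic distances and covalent radii.

    Atoms i, j are bonded iff their distance is at most the covalent-radius
    sum + *tol*.  Each hydrogen is bonded to exactly its nearest heavy atom;
    hydrogens with no heavy atom within 1.3 A are dropped with a warning.
    An explicit bond table already present is kept verbatim.
    """
    if not s.atoms:
        raise EmptyStructureError("cannot infer bonds of an empty structure")
    if s.bonds:
        return s
    if tol is None:
        tol = params.covalent_tolerance

    is_h = np.array([a.element in ("H", "D") for a in s.atoms])
    heavy_idx = np.where(~is_h)[0]
    xyz = s.coords()
    dist = cdist(xyz, xyz)

    bonds: set[tuple[int, int]] = set()
    radii = np.array([params.covalent(a.element) for a in s.atoms])
    for ii, i in enumerate(heavy_idx):
        for j in heavy_idx[ii + 1:]:
            if dist[i, j] <= radii[i] + radii[j] + tol:
                bonds.add((int(i), int(j)))

    orphans = []
    for h in np.where(is_h)[0]:
        if len(heavy_idx) == 0:
            orphans.append(int(h))
            continue
        nearest = heavy_idx[int(np.argmin(dist[h, heavy_idx]))]
        if dist[h, nearest] > 1.3:
            orphans.append(int(h))
        else:
            bonds.add(tuple(sorted((int(h), int(nearest)))))
    if orphans:
        warnings.warn(
            f"{s.id}: dropping {len(orphans)} hydrogen(s) with no heavy atom within 1.3 A"
        )
        keep = [i for i in range(len(s.atoms)) if i not in set(orphans)]
        remap = {old: new for new, old in enumerate(keep)}
        s.atoms = [s.atoms[i] for i in keep]
        bonds = {
            (remap[i], remap[j]) for i, j in bonds if i in remap and j in remap
        }

    s.bonds = sorted(bonds)
    return s


def _op_signature(op_triplet: str, shift: tuple[int, int, int]) -> str:
    return f"{op_triplet}+({shift[0]},{shift[1]},{shift[2]})"


def expand_symmetry(s: CrystalStructure, radius: float | None = None,
                    params: GeometryParams = DEFAULT_PARAMS) -> CrystalStructure:
    """Add symmetry-mate molecules within *radius* of the asymmetric unit.

    Whole covalent molecules are copied, never fragments; identity images
    and copies coinciding with already-present atoms are skipped, which also
    makes the operation idempotent.
    """
    if s.cell is None:
        raise NoSymmetryError(f"{s.id}: no unit cell, cannot expand symmetry")
    if radius is None:
        radius = params.contact_radius
    if not s.bonds and s.atoms:
        infer_bonds(s, params=params)

    asu_idx = [i for i, a in enumerate(s.atoms) if not a.is_symmetry_mate]
    if not asu_idx:
        return s
    asu_xyz = np.array([s.atoms[i].xyz for i in asu_idx])

    existing = {tuple(np.round(a.xyz, 3)) for a in s.atoms}
    comps = [c for c in s.components() if not s.atoms[c[0]].is_symmetry_mate]

    # translation range large enough that no image inside the envelope is missed
    diam = 0.0
    for c in comps:
        pts = np.array([s.atoms[i].xyz for i in c])
        diam = max(diam, float(np.ptp(pts, axis=0).max()))
    reach = radius + diam + 1.0
    tmax = [min(3, max(1, math.ceil(reach / L))) for L in (s.cell.a, s.cell.b, s.cell.c)]

    new_atoms: list[Atom] = []
    new_bonds: list[tuple[int, int]] = []
    for op_str in s.cell.symops:
        op = gemmi.Op(op_str)
        identity = op == gemmi.Op("x,y,z")
        for shift in product(*(range(-t, t + 1) for t in tmax)):
            if identity and shift == (0, 0, 0):
                continue
            for comp in comps:
                frac = []
                for i in comp:
                    a = s.atoms[i]
                    f = a.frac if a.frac is not None else s.cell.fractionalize(a.xyz)
                    frac.append(np.array(op.apply_to_xyz(list(map(float, f)))) + shift)
                xyz = np.array([s.cell.orthogonalize(f) for f in frac])
                if radius <= 0:
                    continue
                dmin = cdist(xyz, asu_xyz).min()
                if dmin > radius:
                    continue
                keys = [tuple(np.round(p, 3)) for p in xyz]
                if all(k in existing for k in keys):
                    continue  # coincides with something already present
                base = len(s.atoms) + len(new_atoms)
                local = {orig: base + k for k, orig in enumerate(comp)}
                sig = _op_signature(op.triplet(), shift)
                for k, orig in enumerate(comp):
                    a = s.atoms[orig]
                    new_atoms.append(
                        Atom(a.label, a.element, xyz[k], frac[k], a.occupancy, True, sig)
                    )
                    existing.add(keys[k])
                for i, j in s.bonds:
                    if i in local and j in local:
                        new_bonds.append((local[i], local[j]))
    s.atoms.extend(new_atoms)
    s.bonds.extend(new_bonds)
    return s


def write_structure(s: CrystalStructure, path: str | Path, format: str = "cif") -> Path:
    """Write *s* as small-molecule CIF or PDB; returns the path written."""
    if not s.atoms:
        raise EmptyStructureError("refusing to write a structure with no atoms")
    path = Path(path)
    if format == "cif":
        _write_cif(s, path)
    elif format == "pdb":
        _write_pdb(s, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _dummy_cell(s: CrystalStructure) -> UnitCell:
    xyz = s.coords()
    span = np.ptp(xyz, axis=0) + 30.0
    return UnitCell(float(span[0]), float(span[1]), float(span[2]), 90.0, 90.0, 90.0)


def _unique_labels(atoms: list[Atom]) -> list[str]:
    seen: dict[str, int] = {}
    labels = []
    for a in atoms:
        n = seen.get(a.label, 0)
        labels.append(a.label if n == 0 else f"{a.label}_{n}")
        seen[a.label] = n + 1
    return labels


def _write_cif(s: CrystalStructure, path: Path) -> None:
    cell = s.cell
    lines = [f"data_{s.id or 'pairdex'}"]
    if cell is None:
        cell = _dummy_cell(s)
        lines.append("# no experimental cell: dummy P1 box for transport only")
    for k, v in zip("abc", (cell.a, cell.b, cell.c)):
        lines.append(f"_cell_length_{k} {v:.4f}")
    for k, v in zip(("alpha", "beta", "gamma"), (cell.alpha, cell.beta, cell.gamma)):
        lines.append(f"_cell_angle_{k} {v:.4f}")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    for op in cell.symops:
        lines.append(f"'{op}'")
    lines.append("loop_")
    for tag in ("label", "type_symbol", "fract_x", "fract_y", "fract_z", "occupancy"):
        lines.append(f"_atom_site_{tag}")
    labels = _unique_labels(s.atoms)
    for a, lbl in zip(s.atoms, labels):
        f = cell.fractionalize(a.xyz)
        lines.append(
            f"{lbl} {a.element} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f} {a.occupancy:.3f}"
        )
    if s.bonds:
        lines.append("loop_")
        lines.append("_geom_bond_atom_site_label_1")
        lines.append("_geom_bond_atom_site_label_2")
        for i, j in s.bonds:
            lines.append(f"{labels[i]} {labels[j]}")
    path.write_text("\n".join(lines) + "\n")


def _write_pdb(s: CrystalStructure, path: Path) -> None:
    lines = []
    if s.cell is not None:
        c = s.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1"
        )
    for i, a in enumerate(s.atoms, start=1):
        name = a.label[:4]
        lines.append(
            f"HETATM{i:5d} {name:<4s} LIG A   1    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{a.occupancy:6.2f}  0.00"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
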