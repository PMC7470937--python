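"""Locate nucleobase moieties in a bonded structure and classify them.

Recognition is heavy-atom subgraph isomorphism of each base template
(elements + ring topology + exocyclic groups) against every covalent
molecule.  A match is kept only when every non-hydrogen substituent sits at
the glycosidic nitrogen (and is a carbon), and no base atom is covalently
bonded to a metal.  The surviving instances are classified by substitution
(R = glycosidic carbon substituent, free = none), by protonation pattern of
the ring nitrogens, and by formal charge relative to the canonical neutral
form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from .chem_templates import (
    BASE_CODES,
    ORGANIC_ELEMENTS,
    BaseTemplate,
    get_template,
    neutral_nh_reference,
    render_pattern,
)
from .structure_io import CrystalStructure


@dataclass
class BaseInstance:
    """One matched nucleobase inside a structure."""

    code: str
    structure: CrystalStructure
    atoms: dict[str, int]            # template atom name -> structure atom index
    hydrogens: dict[str, list[int]]  # template atom name -> attached H indices
    substitution: str = "unknown"    # R | free | unknown
    protonation: str = "?"
    charge: int | None = None
    molecule_id: int = -1
    c1_atom: int | None = None
    nonstandard: list[str] = field(default_factory=list)

    @property
    def template(self) -> BaseTemplate:
        return get_template(self.code)

    @property
    def is_symmetry_mate(self) -> bool:
        return any(self.structure.atoms[i].is_symmetry_mate for i in self.atoms.values())

    def atom_index(self, n: int) -> int:
        """Structure index of the interaction atom for canonical number *n*."""
        return self.atoms[self.template.interaction_atom(n)]

    def xyz(self, n: int) -> np.ndarray:
        return self.structure.atoms[self.atom_index(n)].xyz

    def attached_h(self, n: int) -> list[int]:
        """Hydrogens available for donation from canonical position *n*.

        For thymine's C5 the donation is methyl-mediated, so no directly
        bonded hydrogen is returned and geometry tests on the D-H vector are
        skipped downstream.
        """
        return self.hydrogens.get(self.template.interaction_atom(n), [])

    def ring_xyz(self) -> np.ndarray:
        """Coordinates of the six-membered-ring circuit atoms (plane fitting)."""
        t = self.template
        names = [f"{el}{n}" for n, el in t.ring_atoms[:6]]
        return np.array([self.structure.atoms[self.atoms[nm]].xyz for nm in names])

    def all_heavy_indices(self) -> list[int]:
        return list(self.atoms.values())

    def signature(self) -> tuple:
        return (self.code, tuple(sorted(self.atoms.values())))


def _template_graph(t: BaseTemplate) -> nx.Graph:
    g = nx.Graph()
    ring = dict(t.ring_atoms)
    for n, el in t.ring_atoms:
        g.add_node(f"{el}{n}", element=el)
    for a, b in t.bonds:
        g.add_edge(f"{ring[a]}{a}", f"{ring[b]}{b}")
    for n, el, kind in t.exocyclic_atoms:
        name = f"{el}{7 if kind == 'methyl' else n}"
        g.add_node(name, element=el)
        g.add_edge(name, f"{ring[n]}{n}")
    return g


def _structure_graph(s: CrystalStructure, comp: list[int]) -> nx.Graph:
    g = nx.Graph()
    elements = {i: s.atoms[i].element for i in comp}
    heavy = [i for i in comp if elements[i] not in ("H", "D")]
    g.add_nodes_from((i, {"element": elements[i]}) for i in heavy)
    hs = set(heavy)
    for i, j in s.bonds:
        if i in hs and j in hs:
            g.add_edge(i, j)
    return g


def find_bases(s: CrystalStructure) -> list[BaseInstance]:
    """All nucleobase instances in *s* (bonds must already be present)."""
    nbrs = s.neighbor_map()
    instances: list[BaseInstance] = []
    seen: set[tuple] = set()
    node_match = isomorphism.categorical_node_match("element", None)
    for mol_id, comp in enumerate(s.components()):
        mol_graph = _structure_graph(s, comp)
        if mol_graph.number_of_nodes() < 6:
            continue
        for code in BASE_CODES:
            t = get_template(code)
            tg = _template_graph(t)
            if mol_graph.number_of_nodes() < tg.number_of_nodes():
                continue
            gm = isomorphism.GraphMatcher(mol_graph, tg, node_match=node_match)
            for mapping in gm.subgraph_isomorphisms_iter():
                atoms = {tname: sidx for sidx, tname in mapping.items()}
                key = (code, frozenset(atoms.values()))
                if key in seen:
                    continue
                inst = _vet_match(s, code, atoms, nbrs, mol_id)
                if inst is not None:
                    seen.add(key)
                    instances.append(inst)
    instances.sort(key=lambda b: min(b.atoms.values()))
    return instances


def _vet_match(s, code, atoms, nbrs, mol_id) -> BaseInstance | None:
    t = get_template(code)
    matched = set(atoms.values())
    glyc_idx = atoms[f"N{t.glycosidic_atom}"]
    c1 = None
    hydrogens: dict[str, list[int]] = {name: [] for name in atoms}
    index_to_name = {v: k for k, v in atoms.items()}

    for name, idx in atoms.items():
        for j in nbrs[idx]:
            if j in matched:
                continue
            el = s.atoms[j].element
            if el in ("H", "D"):
                hydrogens[name].append(j)
                continue
            if el not in ORGANIC_ELEMENTS:
                return None  # organometallic: metal bonded to a base atom
            if idx == glyc_idx and el == "C":
                if c1 is not None:
                    return None  # two substituents at the glycosidic N
                c1 = j
                continue
            return None  # non-H substituent outside the glycosidic bond

    inst = BaseInstance(
        code=code,
        structure=s,
        atoms=atoms,
        hydrogens=hydrogens,
        molecule_id=mol_id,
        c1_atom=c1,
    )
    classify_substitution(inst)
    classify_protonation(inst)
    formal_charge(inst)
    return inst


def classify_substitution(b: BaseInstance) -> str:
    """R when the glycosidic nitrogen carries a carbon substituent."""
    b.substitution = "R" if b.c1_atom is not None else "free"
    return b.substitution


def classify_protonation(b: BaseInstance) -> str:
    """Observed protonation pattern text, or ``R?``/``No R?`` when unmodeled.

    Ring-nitrogen H statuses are taken at face value as soon as the base
    carries at least one modeled hydrogen (every base has C-H hydrogens when
    hydrogens were modeled at all); a base with no hydrogen on any of its
    atoms is reported as undetermined rather than imputed.
    """
    t = b.template
    any_h = any(b.hydrogens.get(name) for name in b.atoms)
    for n, el, kind in t.exocyclic_atoms:
        if kind == "carbonyl" and b.hydrogens.get(f"{el}{n}"):
            msg = f"hydrogen on carbonyl {el}{n} of {b.code}"
            b.nonstandard.append(msg)
            warnings.warn(f"nonstandard protonation: {msg}")
    if not any_h:
        b.protonation = render_pattern(b.code, b.substitution, None)
        return b.protonation
    protonated = frozenset(
        n for n in t.ring_n_positions
        if not (b.substitution == "R" and n == t.glycosidic_atom)
        and b.hydrogens.get(f"N{n}")
    )
    b.protonation = render_pattern(b.code, b.substitution, protonated)
    return b.protonation


def formal_charge(b: BaseInstance) -> int | None:
    """Observed ring N-H count minus the neutral reference count."""
    from .chem_templates import parse_pattern

    substitution, protonated = parse_pattern(b.protonation, b.code)
    if protonated is None:
        b.charge = None
        return None
    ref = neutral_nh_reference(b.code, substitution)
    b.charge = len(protonated) - len(ref)
    return b.charge
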