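"""Canonical base-pair names and their Leontis-Westhof correspondence.

A full name looks like ``AA_fWH_(16)(67)``: the two base codes, the
relative orientation of the second base (``f`` flipped / ``m`` moved, i.e.
opposite or same ring face exposed), the interacting edges in
Watson-Crick > Hoogsteen > Sugar precedence order, and one parenthesized
atom-number pair per hydrogen bond with the first molecule's atom first.
The short form drops the middle block (``AA_(16)(67)``).  ``f``/``m``
correspond to ``cis``/``trans`` of the Leontis-Westhof scheme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .chem_templates import EDGE_ORDER, get_template
from .errors import NameParseError, UnclassifiableEdgeError

#: the full homo-pair catalog: 15 adenine, 7 guanine, 5 hypoxanthine,
#: 6 thymine, 7 uracil and 7 cytosine types.
CATALOG_NAMES: tuple[str, ...] = (
    "AA_mWW_(12)(21)",
    "AA_fWW_(16)(21)",
    "AA_mWW_(16)(61)",
    "AA_fWH_(18)(27)",
    "AA_fWH_(16)(67)",
    "AA_fWS_(19)(63)",
    "AA_mHH_(67)(76)",
    "AA_fHH_(67)(78)",
    "AA_mHH_(78)(87)",
    "AA_fHS_(63)(72)",
    "AA_mHS_(63)(79)",
    "AA_mHS_(72)(83)",
    "AA_fHS_(79)(83)",
    "AA_mSS_(23)(32)",
    "AA_mSS_(39)(93)",
    "GG_mWW_(16)(61)",
    "GG_mWH_(16)(27)",
    "GG_fWH_(16)(67)",
    "GG_fWH_(26)(17)(68)",
    "GG_mHH_(67)(76)",
    "GG_mSS_(23)(32)",
    "GG_mSS_(39)(93)",
    "HxHx_mWW_(16)(61)",
    "HxHx_fWH_(17)(26)",
    "HxHx_fWS_(13)(62)",
    "HxHx_fHS_(68)(79)",
    "HxHx_mSS_(23)(32)",
    "TT_mWW_(23)(32)",
    "TT_fWW_(23)(34)",
    "TT_mWW_(34)(43)",
    "TT_fWH_(34)(45)",
    "TT_fWS_(21)(32)",
    "TT_mSS_(12)(21)",
    "UU_mWW_(23)(32)",
    "UU_fWW_(23)(34)",
    "UU_mWW_(34)(43)",
    "UU_fWH_(34)(45)",
    "UU_mHH_(45)(54)",
    "UU_fHS_(41)(52)",
    "UU_mSS_(12)(21)",
    "CC_mWW_(23)(32)",
    "CC_mWW_(24)(33)(42)",
    "CC_mWW_(34)(43)",
    "CC_fWH_(24)(35)",
    "CC_mWH_(25)(34)",
    "CC_fWS_(26)(31)(42)",
    "CC_mSS_(12)(21)",
)


@dataclass(frozen=True)
class PairName:
    codes: tuple[str, str]
    orientation: str            # "f" or "m"
    edges: tuple[str, str]
    bonds: tuple[tuple[int, int], ...]

    @property
    def text(self) -> str:
        b = "".join(f"({a}{c})" for a, c in self.bonds)
        return f"{self.codes[0]}{self.codes[1]}_{self.orientation}{self.edges[0]}{self.edges[1]}_{b}"

    @property
    def short(self) -> str:
        b = "".join(f"({a}{c})" for a, c in self.bonds)
        return f"{self.codes[0]}{self.codes[1]}_{b}"

    def matches(self, other: "PairName") -> bool:
        """Equality up to bond-list ordering (set semantics).

        The catalog spells one three-bond guanine pair with its bonds out of
        ascending order; treating bond lists as sets makes both spellings
        compare equal.
        """
        return (
            self.codes == other.codes
            and self.orientation == other.orientation
            and self.edges == other.edges
            and set(self.bonds) == set(other.bonds)
        )


def assign_edge(code: str, atoms: set[int] | frozenset[int]) -> str:
    """The unique edge containing all *atoms*; W > H > S precedence on ties."""
    if not atoms:
        raise UnclassifiableEdgeError("empty atom set")
    t = get_template(code)
    for e in EDGE_ORDER:
        if set(atoms) <= t.edges[e]:
            return e
    raise UnclassifiableEdgeError(f"no single edge of {code} contains atoms {sorted(atoms)}")


def orientation(b1, b2) -> str:
    """``f`` when the face-labelled ring normals are antiparallel, else ``m``."""
    from .pair_engine import base_plane

    n1, n2 = base_plane(b1)[1], base_plane(b2)[1]
    return "f" if float(np.dot(n1, n2)) < 0 else "m"


def _edge_rank(e: str) -> int:
    return EDGE_ORDER.index(e)


def _is_purine(code: str) -> bool:
    return get_template(code).kind == "purine"


def canonical_name(pr) -> PairName:
    """Build the canonical :class:`PairName` for a detected pair.

    Molecule order follows edge precedence; for equal edges the molecule
    with the lexicographically smaller sorted atom-number list comes first
    (purine-before-pyrimidine, then alphabetical, for hetero pairs); the
    result is invariant under swapping the input base order.
    """
    b1, b2 = pr.base1, pr.base2
    bonds12 = []
    for hb in pr.hbonds:
        if hb.donor_base is b1:
            bonds12.append((hb.d_atom, hb.a_atom))
        else:
            bonds12.append((hb.a_atom, hb.d_atom))
    atoms1 = {a for a, _ in bonds12}
    atoms2 = {c for _, c in bonds12}
    e1, e2 = assign_edge(b1.code, atoms1), assign_edge(b2.code, atoms2)

    def rendered(first_bonds):
        return tuple(sorted(first_bonds))

    swap: bool
    if _edge_rank(e1) != _edge_rank(e2):
        swap = _edge_rank(e1) > _edge_rank(e2)
    elif b1.code != b2.code:
        if _is_purine(b1.code) != _is_purine(b2.code):
            swap = _is_purine(b2.code)
        else:
            swap = b2.code < b1.code
    elif sorted(atoms1) != sorted(atoms2):
        swap = sorted(atoms2) < sorted(atoms1)
    else:
        swap = rendered([(c, a) for a, c in bonds12]) < rendered(bonds12)

    if swap:
        b1, b2 = b2, b1
        e1, e2 = e2, e1
        bonds12 = [(c, a) for a, c in bonds12]

    return PairName(
        codes=(b1.code, b2.code),
        orientation=orientation(b1, b2),
        edges=(e1, e2),
        bonds=tuple(sorted(bonds12)),
    )


_CODE_RE = re.compile(r"Hx|A|G|T|U|C")
_FULL_RE = re.compile(r"^(?P<codes>(?:Hx|[AGTUC]){2})_(?P<orient>[a-z])(?P<e1>[A-Z])(?P<e2>[A-Z])_(?P<bonds>(?:\(\d\d\))+)$")
_SHORT_RE = re.compile(r"^(?P<codes>(?:Hx|[AGTUC]){2})_(?P<bonds>(?:\(\d\d\))+)$")


def _split_codes(text: str) -> tuple[str, str]:
    codes = _CODE_RE.findall(text)
    return codes[0], codes[1]


def _parse_bonds(text: str) -> tuple[tuple[int, int], ...]:
    return tuple((int(m[0]), int(m[1])) for m in re.findall(r"\((\d)(\d)\)", text))


def parse_name(text: str) -> PairName:
    """Parse a full or short pair name into a structured :class:`PairName`."""
    m = _FULL_RE.match(text)
    if m:
        if m.group("orient") not in ("f", "m"):
            raise NameParseError(f"invalid orientation letter {m.group('orient')!r} in {text!r}")
        for e in (m.group("e1"), m.group("e2")):
            if e not in EDGE_ORDER:
                raise NameParseError(f"invalid edge letter {e!r} in {text!r}")
        codes = _split_codes(m.group("codes"))
        bonds = _parse_bonds(m.group("bonds"))
        name = PairName(codes, m.group("orient"), (m.group("e1"), m.group("e2")), bonds)
        # validate atom numbers against the templates' edge maps
        for code, atoms, edge in (
            (codes[0], {a for a, _ in bonds}, name.edges[0]),
            (codes[1], {c for _, c in bonds}, name.edges[1]),
        ):
            t = get_template(code)
            if not atoms <= t.edges[edge]:
                raise NameParseError(
                    f"{text!r}: atoms {sorted(atoms)} are not all on edge {edge} of {code}"
                )
        return name
    m = _SHORT_RE.match(text)
    if m:
        codes = _split_codes(m.group("codes"))
        bonds = _parse_bonds(m.group("bonds"))
        for full in CATALOG_NAMES:
            cand = parse_name(full)
            if cand.codes == codes and set(cand.bonds) == set(bonds):
                return cand
        raise NameParseError(f"short name {text!r} matches no catalog entry")
    raise NameParseError(f"{text!r} does not match the pair-name grammar")


def lw_map(name: PairName) -> tuple[str, str, str]:
    """Map to Leontis-Westhof style (cis/trans, edge1, edge2)."""
    return ("cis" if name.orientation == "f" else "trans", name.edges[0], name.edges[1])
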