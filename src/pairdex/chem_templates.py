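"""Static chemical knowledge about the six nucleobases.

This module owns the canonical numbering of each base, the Watson-Crick /
Hoogsteen / Sugar edge membership of every atom that can take part in a
base-base hydrogen bond, donor/acceptor capabilities as a function of the
observed protonation pattern, and the reference neutral protonation used to
derive formal charges.  Everything is loaded once from the bundled
``data/templates.yaml`` file, which is the single human-editable source of
chemical constants (vdW radii, covalent radii, neutron D-H lengths,
geometric thresholds).

Protonation patterns use the survey notation: ring-nitrogen positions in
ascending order, each number followed by ``H`` when that nitrogen carries a
proton, the glycosidic position followed by ``R`` when it carries a carbon
substituent.  ``"R?"`` and ``"No R?"`` denote substituted/free bases whose
hydrogen positions were not determined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import yaml

from .errors import InconsistentPatternError, UnsupportedBaseError

BASE_CODES = ("A", "G", "Hx", "T", "U", "C")

#: edge precedence used throughout the naming scheme
EDGE_ORDER = ("W", "H", "S")

_UNKNOWN_PATTERNS = ("R?", "No R?")


def _load_data() -> dict:
    with resources.files("pairdex.data").joinpath("templates.yaml").open() as fh:
        return yaml.safe_load(fh)


_DATA = _load_data()


@dataclass(frozen=True)
class BaseTemplate:
    """Topology and ideal geometry of one nucleobase.

    ``ring_atoms`` is the ordered ring circuit (9 atoms for purines, 6 for
    pyrimidines); ``exocyclic_atoms`` lists (position, element, kind) for
    amino/carbonyl/methyl groups; ``coords`` maps atom names (``N1`` ... and
    ``c1p`` for the glycosidic substituent carbon) to ideal in-plane (x, y).
    """

    code: str
    kind: str
    ring_atoms: tuple[tuple[int, str], ...]
    exocyclic_atoms: tuple[tuple[int, str, str], ...]
    glycosidic_atom: int
    bonds: tuple[tuple[int, int], ...]
    edges: dict[str, frozenset[int]]
    neutral_nh: dict[str, frozenset[int]]
    coords: dict[str, tuple[float, float]]

    @property
    def ring_positions(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.ring_atoms)

    @property
    def ring_n_positions(self) -> tuple[int, ...]:
        return tuple(n for n, el in self.ring_atoms if el == "N")

    @property
    def exocyclic_by_position(self) -> dict[int, tuple[str, str]]:
        return {n: (el, kind) for n, el, kind in self.exocyclic_atoms}

    def interaction_atom(self, n: int) -> str:
        """Atom name the canonical number *n* refers to in a pair name.

        Where an exocyclic group sits at position *n* the number denotes the
        exocyclic heavy atom (adenine 6 -> N6, guanine 2 -> N2, uracil 4 ->
        O4 ...); the methyl carbon of thymine is an exception -- number 5
        keeps meaning the ring C5.  Otherwise it is the ring atom itself.
        """
        exo = self.exocyclic_by_position.get(n)
        if exo is not None and exo[1] != "methyl":
            return f"{exo[0]}{n}"
        el = dict(self.ring_atoms)[n]
        return f"{el}{n}"

    def interaction_element(self, n: int) -> str:
        return self.interaction_atom(n)[0]

    @property
    def heavy_atom_names(self) -> tuple[str, ...]:
        names = [f"{el}{n}" for n, el in self.ring_atoms]
        for n, el, kind in self.exocyclic_atoms:
            names.append(f"{el}{7 if kind == 'methyl' else n}")
        return tuple(names)


@dataclass
class GeometryParams:
    """Tunable thresholds of the base-pair search.

    Defaults follow the survey criteria: donor...acceptor within the Bondi
    vdW sum + 1 A, D...A vector within 45 deg of both ring planes, D-H...A
    of at least 120 deg when hydrogens are modeled, and two or more hydrogen
    bonds per pair.
    """

    da_margin: float = _DATA["geometry_defaults"]["da_margin"]
    plane_angle_max: float = _DATA["geometry_defaults"]["plane_angle_max"]
    dha_min: float = _DATA["geometry_defaults"]["dha_min"]
    covalent_tolerance: float = _DATA["geometry_defaults"]["covalent_tolerance"]
    min_hbonds: int = _DATA["geometry_defaults"]["min_hbonds"]
    contact_radius: float = _DATA["geometry_defaults"]["contact_radius"]
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(_DATA["vdw_radii"]))
    covalent_radii: dict[str, float] = field(
        default_factory=lambda: dict(_DATA["covalent_radii"])
    )
    neutron_dh: dict[str, float] = field(default_factory=lambda: dict(_DATA["neutron_dh"]))

    def vdw(self, element: str) -> float:
        return self.vdw_radii.get(element, 1.7)

    def covalent(self, element: str) -> float:
        return self.covalent_radii.get(element, 1.5)

    def copy(self, **kwargs) -> "GeometryParams":
        return replace(self, **kwargs)


DEFAULT_PARAMS = GeometryParams()

#: elements regarded as "organic" -- anything else covalently bonded to a
#: base atom marks the structure organometallic for that base.
ORGANIC_ELEMENTS = frozenset({"H", "D", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "B", "Se"})


@lru_cache(maxsize=None)
def get_template(code: str) -> BaseTemplate:
    """Return the immutable template for one of A, G, Hx, T, U, C."""
    if code not in _DATA["bases"]:
        raise UnsupportedBaseError(f"unknown base code {code!r}; expected one of {BASE_CODES}")
    raw = _DATA["bases"][code]
    return BaseTemplate(
        code=code,
        kind=raw["kind"],
        ring_atoms=tuple((int(n), el) for n, el in raw["ring_atoms"]),
        exocyclic_atoms=tuple((int(n), el, kind) for n, el, kind in raw["exocyclic_atoms"]),
        glycosidic_atom=int(raw["glycosidic_atom"]),
        bonds=tuple((int(a), int(b)) for a, b in raw["bonds"]),
        edges={e: frozenset(v) for e, v in raw["edges"].items()},
        neutral_nh={k: frozenset(v) for k, v in raw["neutral_nh"].items()},
        coords={name: tuple(xy) for name, xy in raw["coords"].items()},
    )


def edges_of_atom(code: str, n: int) -> frozenset[str]:
    """Edges (subset of {W, H, S}) that canonical atom *n* belongs to."""
    t = get_template(code)
    if n not in t.ring_positions:
        raise InconsistentPatternError(f"{code} has no canonical atom {n}")
    return frozenset(e for e in EDGE_ORDER if n in t.edges[e])


def neutral_nh_reference(code: str, substitution: str) -> frozenset[int]:
    """Ring nitrogens protonated in the canonical neutral form."""
    t = get_template(code)
    if substitution not in ("R", "free"):
        raise ValueError(f"substitution must be 'R' or 'free', got {substitution!r}")
    return t.neutral_nh[substitution]


_TOKEN_RE = re.compile(r"^(\d)(H|R)?$")


def parse_pattern(pattern: str, code: str) -> tuple[str, frozenset[int] | None]:
    """Split a protonation pattern into (substitution, protonated ring Ns).

    Returns substitution in {"R", "free"} and the set of protonated ring
    nitrogens, or ``None`` for the undetermined patterns ``"R?"``/``"No R?"``.
    """
    t = get_template(code)
    pattern = pattern.strip()
    if pattern == "R?":
        return "R", None
    if pattern == "No R?":
        return "free", None
    protonated: set[int] = set()
    substituted = False
    seen: set[int] = set()
    for token in pattern.split():
        m = _TOKEN_RE.match(token)
        if not m:
            raise InconsistentPatternError(f"bad token {token!r} in pattern {pattern!r}")
        n, suffix = int(m.group(1)), m.group(2)
        if n not in t.ring_n_positions:
            raise InconsistentPatternError(
                f"{code} pattern {pattern!r} refers to position {n}, not a ring nitrogen"
            )
        if n in seen:
            raise InconsistentPatternError(f"duplicate position {n} in {pattern!r}")
        seen.add(n)
        if suffix == "H":
            protonated.add(n)
        elif suffix == "R":
            if n != t.glycosidic_atom:
                raise InconsistentPatternError(
                    f"R suffix only allowed at the glycosidic position of {code}, got {n}"
                )
            substituted = True
    if seen != set(t.ring_n_positions):
        raise InconsistentPatternError(
            f"pattern {pattern!r} must list every ring nitrogen of {code} exactly once"
        )
    return ("R" if substituted else "free"), frozenset(protonated)


def render_pattern(code: str, substitution: str, protonated: frozenset[int] | None) -> str:
    """Inverse of :func:`parse_pattern`."""
    t = get_template(code)
    if protonated is None:
        return "R?" if substitution == "R" else "No R?"
    parts = []
    for n in sorted(t.ring_n_positions):
        if substitution == "R" and n == t.glycosidic_atom:
            parts.append(f"{n}R")
        elif n in protonated:
            parts.append(f"{n}H")
        else:
            parts.append(str(n))
    return " ".join(parts)


def donor_acceptor_roles(pattern: str, code: str) -> dict[int, frozenset[str]]:
    """Map canonical numbers to their hydrogen-bonding roles.

    Ring nitrogens donate when protonated and accept otherwise; amino
    nitrogens always donate (two protons); carbonyl oxygens always accept;
    ring C-H groups act as weak donors.  Thymine's C5 donates through its
    methyl hydrogens.  For undetermined patterns every ring nitrogen gets
    the donor/acceptor capability union; a glycosidic nitrogen known to be
    substituted has no role at all.
    """
    t = get_template(code)
    substitution, protonated = parse_pattern(pattern, code)
    exo = t.exocyclic_by_position
    roles: dict[int, frozenset[str]] = {}
    for n, el in t.ring_atoms:
        kind = exo.get(n, (None, None))[1]
        if kind in ("amino", "carbonyl"):
            # the number denotes the exocyclic atom, the ring carbon under it
            # is fully substituted and never hydrogen-bonds itself
            roles[n] = frozenset({"donor"} if kind == "amino" else {"acceptor"})
            continue
        if el == "N":
            if substitution == "R" and n == t.glycosidic_atom:
                continue  # blocked by the substituent
            if protonated is None:
                roles[n] = frozenset({"donor", "acceptor"})
            elif n in protonated:
                roles[n] = frozenset({"donor"})
            else:
                roles[n] = frozenset({"acceptor"})
        elif el == "C":
            if kind == "methyl":
                # thymine C5: weak donation mediated by the methyl group
                roles[n] = frozenset({"donor"})
            elif t.kind == "purine" and n in (4, 5):
                continue  # ring-fusion carbons, no H, no role
            else:
                roles[n] = frozenset({"donor"})  # ring C-H, weak donor
    return roles
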