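"""Exception types raised across pairdex."""


class PairdexError(Exception):
    """Base class for all pairdex errors."""


class UnsupportedBaseError(PairdexError):
    """Base code outside {A, G, Hx, T, U, C}."""


class InconsistentPatternError(PairdexError):
    """Protonation pattern refers to atoms the template does not have."""


class FormatError(PairdexError):
    """Structure file could not be parsed."""


class EmptyStructureError(PairdexError):
    """Structure contains no atoms."""


class NoSymmetryError(PairdexError):
    """Symmetry expansion requested without cell/symmetry operators."""


class DegenerateGeometryError(PairdexError):
    """Geometry too degenerate to define a plane."""


class NameParseError(PairdexError):
    """Pair-name text does not match the naming grammar."""


class UnclassifiableEdgeError(PairdexError):
    """No single edge contains all interacting atoms of a base."""


class ConstructionError(PairdexError):
    """Fixture pair geometry could not be realized."""


class SpecError(PairdexError):
    """Fixture specification is chemically contradictory."""
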