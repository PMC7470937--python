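"""Survey statistics: deduplication, frequency tables and geometry summaries.

The survey counts one occurrence per refcode *family* and pair type (a
family is a set of depositions of the same crystal structure, sharing a
six-letter code with differing numeric suffixes), while hydrogen-bond
geometry statistics use every deposition.  Counts are cross-tabulated by
protonation class: the two bases' patterns joined into one header-style
string, ``"R?"``/``"No R?"`` standing for undetermined hydrogens.

Transcriptions of the published per-base count tables ship with the
package (``data/printed_tables``) so the aggregation arithmetic -- grand
totals and category percentages -- can be reproduced exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import PairdexError

_FAMILY_RE = re.compile(r"^([A-Za-z]{6})(\d{2,})$")


@dataclass
class SurveyRecord:
    """One observed base pair in one deposition."""

    structure_id: str
    base: str
    pair_name: str
    protonation_pair: tuple[str, str]
    geometry: dict | None = None
    family: str = ""
    substitution_pair: str = "unknown"
    charge_pair: tuple[int | None, int | None] = (None, None)

    def __post_init__(self):
        if not self.family:
            self.family = family_key(self.structure_id)
        if self.substitution_pair == "unknown":
            self.substitution_pair = _substitution_pair(self.protonation_pair)

    @property
    def protonation_class(self) -> str:
        return protonation_class(self.protonation_pair)

    @property
    def charge_state(self) -> str:
        if any(c is None for c in self.charge_pair):
            return "unknown"
        return "charged" if any(c != 0 for c in self.charge_pair) else "neutral"


def family_key(structure_id: str) -> str:
    """CSD refcode family: the six-letter stem of ``ABCDEF01``-style ids."""
    if not structure_id:
        raise PairdexError("empty structure id")
    m = _FAMILY_RE.match(structure_id)
    return m.group(1) if m else structure_id


def _n_protons(pattern: str) -> int:
    return len(re.findall(r"\dH", pattern))


def protonation_class(patterns: tuple[str, str]) -> str:
    """Header-style class string for a pair of protonation patterns."""
    p1, p2 = patterns
    if p1 == p2:
        return p1
    return " ".join(sorted((p1, p2), key=lambda p: (_n_protons(p), p)))


def _pattern_is_substituted(pattern: str) -> bool | None:
    if pattern == "R?":
        return True
    if pattern == "No R?":
        return False
    return any(tok.endswith("R") for tok in pattern.split())


def _substitution_pair(patterns: tuple[str, str]) -> str:
    subs = {_pattern_is_substituted(p) for p in patterns}
    if subs == {True}:
        return "both R"
    if subs == {False}:
        return "both free"
    return "mixed"


def class_is_substituted(cls: str) -> bool:
    """Whether a protonation-class column belongs to the substituted side."""
    if cls == "No R?":
        return False
    if cls == "R?":
        return True
    return any(tok.endswith("R") for tok in cls.split())


@dataclass
class SurveyTable:
    """Frequency counts plus geometry records for one survey."""

    counts: pd.DataFrame  # index pair_name, columns protonation class
    records: list[SurveyRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy(dtype=float).sum())

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1).astype(int)

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(int)


def tabulate_frequencies(records: list[SurveyRecord]) -> SurveyTable:
    """Count one occurrence per (family, pair type); keep records for geometry.

    A family containing several pair types contributes to each of them; a
    family with several depositions of the same pair type counts once.
    """
    seen: dict[tuple[str, str], SurveyRecord] = {}
    for r in records:
        seen.setdefault((r.family, r.pair_name), r)
    if not seen:
        return SurveyTable(counts=pd.DataFrame(dtype=int), records=[])
    rows = sorted({r.pair_name for r in seen.values()})
    cols: list[str] = []
    for r in seen.values():
        if r.protonation_class not in cols:
            cols.append(r.protonation_class)
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for r in seen.values():
        counts.loc[r.pair_name, r.protonation_class] += 1
    return SurveyTable(counts=counts, records=list(records))


def protonation_crosstab(records: list[SurveyRecord], base: str,
                         impossible: set[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pair-type x protonation-class table with Sum margins.

    Cells listed in *impossible* render as ``"-"`` (pair type cannot form
    under that protonation); everything else is an integer count.
    """
    table = tabulate_frequencies([r for r in records if r.base == base])
    counts = table.counts
    out = counts.copy().astype(object)
    if impossible:
        for row, col in impossible:
            if row in out.index and col in out.columns:
                out.loc[row, col] = "-"
    out["Sum"] = table.row_sums()
    sums = table.column_sums()
    sums["Sum"] = table.total
    out.loc["Sum"] = sums
    return out


def geometry_stats(records: list[SurveyRecord], pair_name: str) -> dict[str, dict]:
    """Per bond-class n/mean/sd/min/max over normalized geometries.

    Every deposition contributes; records lacking hydrogens contribute to
    D...A but not to D-H / H...A / D-H...A statistics.
    """
    per_class: dict[str, dict[str, list[float]]] = {}
    c1c1: list[float] = []
    for r in records:
        if r.pair_name != pair_name or not r.geometry:
            continue
        if r.geometry.get("c1_c1") is not None:
            c1c1.append(r.geometry["c1_c1"])
        for b in r.geometry.get("bonds", []):
            acc = per_class.setdefault(
                b["class"], {"d_a": [], "d_h": [], "h_a": [], "dha": []}
            )
            for k in acc:
                if b.get(k) is not None:
                    acc[k].append(float(b[k]))
    out: dict[str, dict] = {}
    for cls, acc in per_class.items():
        out[cls] = {}
        for k, vals in acc.items():
            if not vals:
                continue
            out[cls][k] = {
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                "min": float(min(vals)),
                "max": float(max(vals)),
            }
    if c1c1:
        out["c1_c1"] = {
            "n": len(c1c1),
            "mean": float(np.mean(c1c1)),
            "sd": float(np.std(c1c1, ddof=1)) if len(c1c1) > 1 else None,
            "min": float(min(c1c1)),
            "max": float(max(c1c1)),
        }
    return out


def percentage(t: SurveyTable, pair_name: str, category: str = "all") -> float:
    """Share (%) of *pair_name* within a frequency category.

    ``substituted`` sums the columns with an R substituent (including
    ``"R?"``), ``free`` the rest (including ``"No R?"``), ``all`` both.
    """
    if category not in ("all", "substituted", "free"):
        raise ValueError(f"unknown category {category!r}")
    if category == "all":
        cols = list(t.counts.columns)
    else:
        want = category == "substituted"
        cols = [c for c in t.counts.columns if class_is_substituted(c) == want]
    sub = t.counts[cols]
    denom = float(sub.to_numpy(dtype=float).sum())
    if denom == 0:
        raise PairdexError(f"category {category!r} has zero total")
    num = float(sub.loc[pair_name].sum()) if pair_name in sub.index else 0.0
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# bundled transcriptions of the published per-base count tables


def load_printed_table(base: str) -> pd.DataFrame:
    """Raw transcription: index pair rows, header-string columns, cells
    int / ``"-"`` (cannot form) / ``"NA"`` (substituent forbids)."""
    path = resources.files("pairdex.data").joinpath(f"printed_tables/{base}.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0, dtype=str, keep_default_na=False)


def printed_records(base: str) -> list[SurveyRecord]:
    """Expand a printed table into one synthetic record per counted family."""
    df = load_printed_table(base)
    records = []
    serial = 0
    for pair_name, row in df.iterrows():
        for cls, cell in row.items():
            if cell in ("-", "NA"):
                continue
            n = int(cell)
            patterns = _class_to_patterns(cls)
            for _ in range(n):
                serial += 1
                records.append(
                    SurveyRecord(
                        structure_id=f"{base}#{serial:04d}",
                        base=base,
                        pair_name=pair_name,
                        protonation_pair=patterns,
                    )
                )
    return records


def printed_impossible(base: str) -> set[tuple[str, str]]:
    """(row, column) cells the printed table marks as unable to form."""
    df = load_printed_table(base)
    out = set()
    for pair_name, row in df.iterrows():
        for cls, cell in row.items():
            if cell in ("-", "NA"):
                out.add((pair_name, cls))
    return out


def _class_to_patterns(cls: str) -> tuple[str, str]:
    """Invert :func:`protonation_class` for the printed header strings."""
    if cls in ("R?", "No R?"):
        return (cls, cls)
    tokens = cls.split()
    # a two-pattern class repeats position "1": split before the second "1..."
    first_positions = [i for i, tok in enumerate(tokens) if tok[0] == "1"]
    if len(first_positions) == 2:
        i = first_positions[1]
        return (" ".join(tokens[:i]), " ".join(tokens[i:]))
    return (cls, cls)
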