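"""N-glycan composition model: parsing, mass calculus, classification, diagnostic ions.

Compositions are written in the field's bracket notation, e.g.

    (Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)4 + (Man)3(GlcNAc)2

where the segment after ``+`` is the invariant N-glycan core (Man3GlcNAc2).
For mass and counting purposes core Man is folded into Hex and core GlcNAc
into HexNAc; the core segment is retained for display and for recognising
high-mannose structures.  Compositions carry no topology: the pipeline never
infers linkage or isomer structure, only monosaccharide counts.

O-acetylation of sialic acids is modelled as a per-composition count
(``acetyl_count`` <= NeuAc count) rather than a localised modification,
because upstream glycopeptide search engines generally report the +42 Da
increment without localising it to a specific NeuAc.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "MONOSACCHARIDES",
    "WATER",
    "PROTON",
    "ACETYL",
    "DEAMIDATION",
    "GlycanComposition",
    "GlycanClass",
    "CompositionParseError",
    "parse_composition",
    "format_composition",
    "composition_mass",
    "classify",
    "neuac_count",
    "diagnostic_ions",
]

# Monoisotopic residue masses (Da).  These are the standard values that
# reproduce the printed oxonium-ion m/z of the sialic-dimer series and the
# O-acetyl-NeuAc diagnostic pair.
MONOSACCHARIDES: Mapping[str, float] = MappingProxyType(
    {
        "Hex": 162.05282,
        "HexNAc": 203.07937,
        "Deoxyhexose": 146.05791,
        "NeuAc": 291.09542,
    }
)

WATER = 18.010565  # Da, monoisotopic
PROTON = 1.00728  # Da
ACETYL = 42.010565  # Da, C2H2O — the O-acetyl increment on NeuAc
DEAMIDATION = 0.984016  # Da, Asn -> Asp after PNGase F release

# Core-segment symbols map onto the generic hexose/HexNAc classes for mass.
_CORE_ALIASES = {"Man": "Hex", "GlcNAc": "HexNAc"}

# Canonical token order for formatting.
_SYMBOL_ORDER = ("Hex", "HexNAc", "Deoxyhexose", "NeuAc")

_TOKEN_RE = re.compile(r"\(\s*([A-Za-z0-9]+)\s*\)\s*(-?\d+)")


class CompositionParseError(ValueError):
    """Raised when a composition string violates the grammar."""


@dataclass(frozen=True)
class GlycanClass:
    """Two-way type split plus decoration flags.

    ``type_label`` is ``"high-mannose"`` or ``"hybrid/complex"``; hybrid and
    complex are not separated because intact-glycopeptide data without
    topology cannot distinguish them reliably.
    """

    type_label: str
    fucosylated: bool
    sialylated: bool


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide count vector with optional O-acetyl count and core segment.

    ``counts`` holds *total* counts (core included).  ``core`` records the
    ``+ (Man)a(GlcNAc)b`` segment as written, for lossless round-tripping.
    """

    counts: Mapping[str, int]
    acetyl_count: int = 0
    core: Mapping[str, int] = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        counts = {s: int(n) for s, n in self.counts.items() if n}
        core = {s: int(n) for s, n in self.core.items() if n}
        for sym, n in counts.items():
            if sym not in MONOSACCHARIDES:
                raise CompositionParseError(f"unknown monosaccharide symbol: {sym!r}")
            if n < 0:
                raise CompositionParseError(f"negative count for {sym!r}")
        for sym, n in core.items():
            if sym not in _CORE_ALIASES:
                raise CompositionParseError(f"unknown core symbol: {sym!r}")
            if n < 0:
                raise CompositionParseError(f"negative core count for {sym!r}")
        if counts.get("Hex", 0) < core.get("Man", 0):
            raise CompositionParseError("total Hex smaller than core Man count")
        if counts.get("HexNAc", 0) < core.get("GlcNAc", 0):
            raise CompositionParseError("total HexNAc smaller than core GlcNAc count")
        if self.acetyl_count < 0:
            raise ValueError("acetyl_count must be non-negative")
        if self.acetyl_count > counts.get("NeuAc", 0):
            raise ValueError("acetyl_count exceeds NeuAc count")
        object.__setattr__(self, "counts", MappingProxyType(counts))
        object.__setattr__(self, "core", MappingProxyType(core))

    def total(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __str__(self) -> str:  # pragma: no cover - delegation
        return format_composition(self)

    # Frozen dataclass with mapping fields: define identity by value.
    def key(self) -> tuple:
        return (
            tuple(sorted(self.counts.items())),
            self.acetyl_count,
            tuple(sorted(self.core.items())),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def with_acetyl(self, n: int) -> "GlycanComposition":
        return GlycanComposition(dict(self.counts), acetyl_count=n, core=dict(self.core), id=self.id)


def _parse_segment(segment: str, allowed: Mapping[str, float] | dict, what: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    segment = segment.strip()
    while pos < len(segment):
        m = _TOKEN_RE.match(segment, pos)
        if m is None:
            raise CompositionParseError(
                f"malformed {what} token at: {segment[pos:pos + 20]!r}"
            )
        sym, n_str = m.group(1), m.group(2)
        n = int(n_str)
        if sym not in allowed:
            raise CompositionParseError(f"unknown monosaccharide symbol in {what}: ({sym}){n_str}")
        if n <= 0:
            raise CompositionParseError(f"non-positive count in {what}: ({sym}){n_str}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
        while pos < len(segment) and segment[pos].isspace():
            pos += 1
    return counts


def parse_composition(text: str, id: str | None = None, acetyl_count: int = 0) -> GlycanComposition:
    """Parse a composition string into a :class:`GlycanComposition`.

    The grammar is one or more ``(Symbol)count`` tokens, optionally followed
    by ``+`` and core tokens.  Counts are positive integers; unknown symbols
    are rejected with the offending token named.  Total counts include the
    core segment (core Man counted as Hex, core GlcNAc as HexNAc).

    >>> c = parse_composition("(Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)4 + (Man)3(GlcNAc)2")
    >>> c.total("Hex"), c.total("HexNAc")
    (5, 4)
    """
    if not isinstance(text, str):
        raise CompositionParseError("composition must be a string")
    parts = text.split("+")
    if len(parts) > 2:
        raise CompositionParseError(f"more than one '+' in composition: {text!r}")
    antenna_txt = parts[0]
    core_txt = parts[1] if len(parts) == 2 else ""

    counts = _parse_segment(antenna_txt, MONOSACCHARIDES, "composition") if antenna_txt.strip() else {}
    core = _parse_segment(core_txt, _CORE_ALIASES, "core") if core_txt.strip() else {}
    if len(parts) == 2 and not core:
        raise CompositionParseError(f"'+' with empty core segment: {text!r}")
    if not counts and not core:
        raise CompositionParseError(f"empty composition string: {text!r}")

    for sym, n in core.items():
        tgt = _CORE_ALIASES[sym]
        counts[tgt] = counts.get(tgt, 0) + n
    return GlycanComposition(counts, acetyl_count=acetyl_count, core=core, id=id)


def format_composition(comp: GlycanComposition) -> str:
    """Canonical string form: ``(Sym)n`` tokens separated by single spaces,
    core appended after `` + `` with its tokens unspaced, zero counts omitted."""
    antenna = dict(comp.counts)
    for sym, n in comp.core.items():
        tgt = _CORE_ALIASES[sym]
        antenna[tgt] = antenna.get(tgt, 0) - n
    tokens = [f"({s}){antenna[s]}" for s in _SYMBOL_ORDER if antenna.get(s, 0) > 0]
    head = " ".join(tokens)
    if comp.core:
        core_str = "".join(
            f"({s}){comp.core[s]}" for s in ("Man", "GlcNAc") if comp.core.get(s, 0) > 0
        )
        return f"{head} + {core_str}" if head else f"+ {core_str}"
    return head


def composition_mass(comp: GlycanComposition, as_free_glycan: bool = False) -> float:
    """Monoisotopic mass in Da.

    The residue-sum mass is the glycan's contribution when attached to a
    peptide; the free (released) glycan carries one additional water.
    """
    mass = sum(MONOSACCHARIDES[s] * n for s, n in comp.counts.items())
    mass += comp.acetyl_count * ACETYL
    if as_free_glycan:
        mass += WATER
    return mass


def classify(comp: GlycanComposition) -> GlycanClass:
    """Two-way classification plus fucosylation/sialylation flags.

    High-mannose: exactly the two core GlcNAc residues (total HexNAc == 2),
    no deoxyhexose, no sialic acid, and at least five hexoses (Man5 and up).
    Everything else is hybrid/complex.
    """
    fuc = comp.total("Deoxyhexose") >= 1
    sia = comp.total("NeuAc") >= 1
    if comp.total("HexNAc") == 2 and not fuc and not sia and comp.total("Hex") >= 5:
        return GlycanClass("high-mannose", False, False)
    return GlycanClass("hybrid/complex", fuc, sia)


def neuac_count(comp: GlycanComposition) -> int:
    """Number of sialic acid (NeuAc) units in the composition."""
    return comp.total("NeuAc")


_ION_KINDS = {
    "neuac": MONOSACCHARIDES["NeuAc"],
    "acetyl_neuac": MONOSACCHARIDES["NeuAc"] + ACETYL,
    "neuac_dimer": 2 * MONOSACCHARIDES["NeuAc"],
}


def diagnostic_ions(kind: str, n_water_losses: int = 0) -> float:
    """Singly protonated oxonium-ion m/z for NeuAc-derived fragments.

    ``neuac_dimer`` with 0/1/2 water losses yields the m/z 583/565/547 series
    diagnostic of a NeuAc-NeuAc antenna; ``acetyl_neuac`` with 0/1 losses
    yields the 334.113/316.103 pair diagnostic of O-acetylated sialic acid.
    """
    if kind not in _ION_KINDS:
        raise ValueError(f"unsupported diagnostic ion kind: {kind!r}")
    if n_water_losses not in (0, 1, 2):
        raise ValueError(f"unsupported water-loss count: {n_water_losses!r}")
    return _ION_KINDS[kind] + PROTON - n_water_losses * WATER
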