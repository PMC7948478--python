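"""N-glycan composition algebra.

An N-glycan composition is summarized by four residue counts — HexNAc
(N-acetylhexosamine), Hex (hexose), dHex (deoxyhexose, i.e. fucose) and
NeuAc (N-acetylneuraminic acid) — the standard four-number notation of
glycoproteomics reports. Compositions carry no topology: isobaric
structures (e.g. a bisecting GlcNAc vs. an antenna GlcNAc) are not
distinguished, so the oligomannose / hybrid / complex / truncated call is
a composition heuristic, implemented as a declarative, user-replaceable
rule table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "GlycanComposition",
    "ClassRule",
    "DEFAULT_CLASS_RULES",
    "RESIDUE_FORMULAS",
    "parse_composition",
    "format_composition",
    "glycan_delta_mass",
    "classify_glycan",
]

#: Elemental formulas of glycosyl *residues* (monosaccharide minus water),
#: i.e. the mass each residue adds to a peptide or growing glycan.
RESIDUE_FORMULAS = {
    "hexnac": _pmass.Composition(formula="C8H13NO5"),
    "hex": _pmass.Composition(formula="C6H10O5"),
    "dhex": _pmass.Composition(formula="C6H10O4"),
    "neuac": _pmass.Composition(formula="C11H17NO8"),
}

_FIELD_ORDER = ("hexnac", "hex", "dhex", "neuac")
_NAME_ALIASES = {
    "hexnac": "hexnac",
    "hex": "hex",
    "dhex": "dhex",
    "fuc": "dhex",
    "neuac": "neuac",
}


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of HexNAc, Hex, dHex and NeuAc residues.

    Ordering and hashing follow the (HexNAc, Hex, dHex, NeuAc) tuple, the
    same field order used by the four-number display notation, so sorting
    compositions gives the conventional lexicographic tie-break.
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in _FIELD_ORDER:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(
                    f"residue count {name}={v!r} must be a non-negative integer"
                )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hexnac, self.hex, self.dhex, self.neuac)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.dhex + other.dhex,
            self.neuac + other.neuac,
        )

    @property
    def formula(self) -> _pmass.Composition:
        """Total elemental formula added to the peptide by this glycan."""
        total = _pmass.Composition()
        for name in _FIELD_ORDER:
            n = getattr(self, name)
            if n:
                total += RESIDUE_FORMULAS[name] * n
        return total

    def __str__(self) -> str:
        return format_composition(self)


_LONG_TOKEN = re.compile(r"([A-Za-z]+)\((-?\d+)\)")
_SHORT_FORM = re.compile(r"^\s*(-?\d+)\s*,\s*(-?\d+)\s*,\s*(-?\d+)\s*,\s*(-?\d+)\s*$")


def parse_composition(text: str) -> GlycanComposition:
    """Parse ``"HexNAc(a)Hex(b)dHex(c)NeuAc(d)"`` or ``"a,b,c,d"`` notation.

    Residue classes omitted from the long form default to zero. Raises
    ``ValueError`` naming the offending token on malformed input or
    negative counts.
    """
    short = _SHORT_FORM.match(text)
    if short:
        return GlycanComposition(*(int(g) for g in short.groups()))

    counts = dict.fromkeys(_FIELD_ORDER, 0)
    pos = 0
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty composition string")
    for m in _LONG_TOKEN.finditer(stripped):
        if m.start() != pos:
            raise ValueError(f"malformed composition near {stripped[pos:m.start()]!r}")
        name = _NAME_ALIASES.get(m.group(1).lower())
        if name is None:
            raise ValueError(f"unknown residue class {m.group(1)!r}")
        counts[name] = int(m.group(2))
        pos = m.end()
    if pos != len(stripped):
        raise ValueError(f"malformed composition near {stripped[pos:]!r}")
    return GlycanComposition(**counts)


def format_composition(c: GlycanComposition, style: str = "short") -> str:
    """Render a composition; ``short`` is the four-number display notation."""
    if style == "short":
        return ",".join(str(v) for v in c.as_tuple())
    if style == "long":
        names = {"hexnac": "HexNAc", "hex": "Hex", "dhex": "dHex", "neuac": "NeuAc"}
        return "".join(
            f"{names[f]}({getattr(c, f)})" for f in _FIELD_ORDER if getattr(c, f)
        ) or "HexNAc(0)"
    raise ValueError(f"unknown style {style!r}")


def glycan_delta_mass(c: GlycanComposition) -> float:
    """Monoisotopic mass shift (Da) the glycan adds to a peptide.

    Computed from the residue elemental formulas against the shared atomic
    mass table, never from hard-coded residue masses.
    """
    return sum(
        getattr(c, name) * _pmass.calculate_mass(RESIDUE_FORMULAS[name])
        for name in _FIELD_ORDER
    )


@dataclass(frozen=True)
class ClassRule:
    """One row of the classification table: bounds on residue counts.

    ``None`` bounds are unconstrained. ``decorations_min`` bounds the sum
    dHex + NeuAc (terminal decorations), used to pull decorated
    two-HexNAc compositions out of the oligomannose class. Rules are
    evaluated in order; the first match wins, so a final catch-all row
    makes the table a total partition.
    """

    label: str
    hexnac_min: int | None = None
    hexnac_max: int | None = None
    hex_min: int | None = None
    hex_max: int | None = None
    dhex_max: int | None = None
    neuac_max: int | None = None
    decorations_min: int | None = None

    def matches(self, c: GlycanComposition) -> bool:
        checks = (
            (self.hexnac_min, c.hexnac, "ge"),
            (self.hexnac_max, c.hexnac, "le"),
            (self.hex_min, c.hex, "ge"),
            (self.hex_max, c.hex, "le"),
            (self.dhex_max, c.dhex, "le"),
            (self.neuac_max, c.neuac, "le"),
            (self.decorations_min, c.dhex + c.neuac, "ge"),
        )
        for bound, value, sense in checks:
            if bound is None:
                continue
            if sense == "ge" and value < bound:
                return False
            if sense == "le" and value > bound:
                return False
        return True


#: Composition-level maturity heuristic. Truncated: core fragments below
#: Man5 with no antenna GlcNAc. Oligomannose: core 2 HexNAc with >=5 Hex
#: and no decorations. Hybrid: one antenna GlcNAc with a retained mannose
#: arm, or a decorated Man>=5 composition. Complex: everything else.
DEFAULT_CLASS_RULES: tuple[ClassRule, ...] = (
    ClassRule("truncated", hexnac_max=2, hex_max=4),
    ClassRule("oligomannose", hexnac_min=2, hexnac_max=2, hex_min=5,
              dhex_max=0, neuac_max=0),
    ClassRule("hybrid", hexnac_min=3, hexnac_max=3, hex_min=5),
    ClassRule("hybrid", hexnac_min=2, hexnac_max=2, hex_min=5,
              decorations_min=1),
    ClassRule("complex"),
)

GLYCAN_CLASSES = ("oligomannose", "hybrid", "complex", "truncated")


def classify_glycan(
    c: GlycanComposition,
    rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES,
) -> str:
    """Assign a maturity class by first-match against the rule table.

    With the default table every composition receives exactly one class
    (the last row is a catch-all), so the classification is a total
    partition of composition space.
    """
    for rule in rules:
        if rule.matches(c):
            return rule.label
    raise ValueError(f"rule table does not cover composition {c}")


def enumerate_compositions(
    hexnac: Iterable[int],
    hex_: Iterable[int],
    dhex: Iterable[int],
    neuac: Iterable[int],
    biosynthetic_pruning: bool = True,
) -> list[GlycanComposition]:
    """Grid of candidate compositions for a targeted search.

    ``biosynthetic_pruning`` drops compositions with more sialic acids
    than available antenna GlcNAcs (NeuAc > max(0, HexNAc - 2)), which a
    mammalian biosynthetic pathway cannot produce.
    """
    out = []
    for a in hexnac:
        for b in hex_:
            for c in dhex:
                for d in neuac:
                    if biosynthetic_pruning and d > max(0, a - 2):
                        continue
                    out.append(GlycanComposition(a, b, c, d))
    return out
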