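"""Protein handling: sequons, in-silico proteolysis, glycopeptide masses.

The digestion model is a combined specificity set for a two-protease
digest (chymotrypsin F/W/Y/L plus Glu-C at E under ammonium-bicarbonate
conditions): cleavage C-terminal to any residue in the set, suppressed
when the next residue is proline, with up to ``max_missed`` internal
sites retained. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Mapping, Sequence

from pyteomics import mass as _pmass

from .glycans import GlycanComposition, glycan_delta_mass

__all__ = [
    "GlycoSite",
    "Peptide",
    "Glycopeptide",
    "CHYMOTRYPSIN",
    "GLUC",
    "DEFAULT_SPECIFICITY",
    "CARBAMIDOMETHYL_MASS",
    "find_sequons",
    "digest",
    "peptide_mass",
    "glycopeptide_mass",
    "glycopeptide_mz",
]

PROTON_MASS = 1.00727646677
WATER = _pmass.Composition(formula="H2O")

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), the fixed
#: modification applied after reduction in the sample-prep model.
CARBAMIDOMETHYL_FORMULA = _pmass.Composition(formula="C2H3NO")
CARBAMIDOMETHYL_MASS = _pmass.calculate_mass(CARBAMIDOMETHYL_FORMULA)
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL_MASS}

CHYMOTRYPSIN: FrozenSet[str] = frozenset("FWYL")
GLUC: FrozenSet[str] = frozenset("E")  # D optional, bicarbonate convention
DEFAULT_SPECIFICITY: FrozenSet[str] = CHYMOTRYPSIN | GLUC

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _check_sequence(protein: str) -> None:
    bad = set(protein) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(bad)}")


@dataclass(frozen=True)
class GlycoSite:
    """An N-glycosylation sequon in the supplied sequence.

    ``position`` is the 1-based index of the asparagine; ``label`` is the
    reported site name (e.g. ``"N162"``), which may differ from the raw
    position when the reported numbering refers to the mature protein.
    """

    position: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("sequence_position is 1-based")
        if not self.label:
            object.__setattr__(self, "label", f"N{self.position}")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with parent-protein coordinates."""

    sequence: str
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0
    fixed_mods: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_FIXED_MODS.items())
    )

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide carrying one intact N-glycan at one sequon.

    Peptides with several sequons are rejected: with a single sequon the
    glycoform can be assigned to one site without a localization step.
    """

    peptide: Peptide
    site: GlycoSite
    glycan: GlycanComposition

    def __post_init__(self) -> None:
        if not self.peptide.covers(self.site.position):
            raise ValueError(
                f"site {self.site.label} at {self.site.position} outside "
                f"peptide {self.peptide.start}-{self.peptide.end}"
            )
        n_sequons = len(find_sequons(self.peptide.sequence))
        if n_sequons != 1:
            raise ValueError(
                f"site-resolved quantification requires exactly one sequon "
                f"per peptide, found {n_sequons} in {self.peptide.sequence!r}"
            )


def find_sequons(protein: str, site_labels: Mapping[int, str] | None = None
                 ) -> list[GlycoSite]:
    """All N-X-S/T sequons (X != P) in order of position.

    ``site_labels`` maps 1-based positions to reported names; unlabeled
    sites get ``"N<position>"``.
    """
    _check_sequence(protein)
    sites = []
    for i in range(len(protein) - 2):
        if (protein[i] == "N" and protein[i + 1] != "P"
                and protein[i + 2] in "ST"):
            pos = i + 1
            label = (site_labels or {}).get(pos, "")
            sites.append(GlycoSite(pos, label))
    return sites


def digest(
    protein: str,
    specificity: FrozenSet[str] = DEFAULT_SPECIFICITY,
    max_missed: int = 2,
) -> list[Peptide]:
    """All peptides from cleavage C-terminal to ``specificity`` residues.

    Cleavage is suppressed before proline. Peptides retaining up to
    ``max_missed`` internal cleavage sites are included, ordered by start
    then end coordinate.
    """
    if not protein:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    _check_sequence(protein)

    # cut points: index i means a cut between protein[i-1] and protein[i]
    cuts = [0]
    for i in range(1, len(protein)):
        if protein[i - 1] in specificity and protein[i] != "P":
            cuts.append(i)
    cuts.append(len(protein))

    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(cuts))):
            s, e = cuts[a], cuts[b]
            peptides.append(
                Peptide(protein[s:e], start=s + 1, end=e,
                        missed_cleavages=b - a - 1)
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(p: Peptide | str) -> float:
    """Neutral monoisotopic mass: residue masses + water + fixed mods."""
    if isinstance(p, str):
        p = Peptide(p)
    base = _pmass.calculate_mass(sequence=p.sequence) if p.sequence else \
        _pmass.calculate_mass(WATER)
    mods = sum(p.sequence.count(res) * shift for res, shift in p.fixed_mods)
    return base + mods


def glycopeptide_mass(gp: Glycopeptide) -> float:
    """Neutral monoisotopic mass of the intact glycopeptide."""
    return peptide_mass(gp.peptide) + glycan_delta_mass(gp.glycan)


def glycopeptide_mz(
    gp: Glycopeptide | float,
    z: int,
    scan_range: tuple[float, float] = (600.0, 2500.0),
) -> tuple[float, bool]:
    """Precursor m/z at charge ``z`` and an in-scan-range flag.

    Accepts either a glycopeptide or a precomputed neutral mass. The
    default range is the glycopeptide acquisition window 600-2500 m/z.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    neutral = gp if isinstance(gp, (int, float)) else glycopeptide_mass(gp)
    mz = (neutral + z * PROTON_MASS) / z
    in_range = scan_range[0] <= mz <= scan_range[1]
    return mz, in_range


def single_sequon_glycopeptides(
    protein: str,
    sites: Sequence[GlycoSite] | None = None,
    specificity: FrozenSet[str] = DEFAULT_SPECIFICITY,
    max_missed: int = 2,
) -> list[tuple[Peptide, GlycoSite]]:
    """(peptide, site) pairs where the peptide contains exactly one sequon.

    This is the backbone library for the targeted glycopeptide search.
    """
    if sites is None:
        sites = find_sequons(protein)
    out = []
    for pep in digest(protein, specificity, max_missed):
        # the whole N-X-S/T motif must lie inside the peptide
        covered = [s for s in sites
                   if pep.start <= s.position and s.position + 2 <= pep.end]
        if len(covered) == 1 and len(find_sequons(pep.sequence)) == 1:
            out.append((pep, covered[0]))
    return out
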