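"""Targeted glycopeptide identification and MS2 validation.

The search is targeted: candidates come from an in-silico library built
as (single-sequon digest peptides) x (glycan composition grid) for the
one protein under study. A candidate is assigned to an MS2 spectrum by
precursor mass match and then validated against the spectrum using the
manual criteria of glycoproteomics practice: glycan oxonium ions must be
present, and the peptide backbone must be evidenced either by the Y1 ion
(peptide + one GlcNAc) or by y/b backbone fragment coverage. No FDR is
estimated — the search space is a single protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pmass

from .glycans import (GlycanComposition, RESIDUE_FORMULAS,
                      enumerate_compositions)
from .peptides import (PROTON_MASS, Glycopeptide, Peptide,
                       glycopeptide_mass, peptide_mass,
                       single_sequon_glycopeptides)
from .spectra import Run, Spectrum

__all__ = [
    "IdentifyConfig", "ValidationResult", "Identification",
    "OXONIUM_MZ", "match_precursor", "detect_oxonium", "detect_y1",
    "match_backbone", "validate", "build_library", "search_run",
]

_WATER = _pmass.calculate_mass(formula="H2O")
_HEXNAC = _pmass.calculate_mass(RESIDUE_FORMULAS["hexnac"])
_HEX = _pmass.calculate_mass(RESIDUE_FORMULAS["hex"])
_NEUAC = _pmass.calculate_mass(RESIDUE_FORMULAS["neuac"])

#: Diagnostic oxonium (glycosyl cation) m/z values, computed from the
#: residue elemental formulas: residue + proton, minus neutral losses.
OXONIUM_MZ = {
    "HexNAc": _HEXNAC + PROTON_MASS,
    "HexNAc-H2O": _HEXNAC - _WATER + PROTON_MASS,
    "HexNAc-2H2O": _HEXNAC - 2 * _WATER + PROTON_MASS,
    "HexNAc-C2H6O3": _HEXNAC - 2 * _WATER
        - _pmass.calculate_mass(formula="CH2O") + PROTON_MASS,
    "HexHexNAc": _HEXNAC + _HEX + PROTON_MASS,
    "NeuAc": _NEUAC + PROTON_MASS,
    "NeuAc-H2O": _NEUAC - _WATER + PROTON_MASS,
}


@dataclass(frozen=True)
class IdentifyConfig:
    """Tolerances and rules of the identification stage.

    ``precursor_tol_da`` defaults to the 0.015 window also used for MS1
    peak selection; ``y1_charges`` are the charge states tried for the
    peptide+GlcNAc ion.
    """

    precursor_tol_da: float = 0.015
    oxonium_tol_mz: float = 0.02
    fragment_tol_mz: float = 0.02
    backbone_min_coverage: float = 0.25
    y1_charges: tuple[int, ...] = (1, 2)
    precursor_charges: tuple[int, ...] = (2, 3, 4)
    require_oxonium: bool = True


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of MS2 validation of one candidate against one spectrum."""

    precursor_error_da: float
    oxonium_found: bool
    oxonium_matched: tuple[str, ...]
    y1_found: bool
    backbone_coverage: float
    peptide_glycan_ions: int
    accepted: bool


@dataclass(frozen=True)
class Identification:
    """An accepted (or best rejected) candidate for one MS2 spectrum."""

    glycopeptide: Glycopeptide
    z: int
    rt: float
    scan: int
    result: ValidationResult


def _has_peak(s: Spectrum, mz: float, tol: float) -> bool:
    i = np.searchsorted(s.mz, mz)
    for j in (i - 1, i):
        if 0 <= j < len(s.mz) and abs(s.mz[j] - mz) <= tol:
            return True
    return False


def match_precursor(obs_mz: float, z: int, gp: Glycopeptide | float,
                    tol_da: float = 0.015) -> tuple[float, bool]:
    """Observed-minus-theoretical neutral mass error (Da) and a
    within-tolerance flag. Accepts a glycopeptide or a neutral mass."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    theo = gp if isinstance(gp, (int, float)) else glycopeptide_mass(gp)
    error = z * (obs_mz - PROTON_MASS) - theo
    return error, abs(error) <= tol_da


def detect_oxonium(s: Spectrum, tol_mz: float = 0.02) -> tuple[str, ...]:
    """Names of diagnostic oxonium ions present within ``tol_mz``."""
    if s.ms_level != 2:
        raise ValueError("oxonium detection needs an MS2 spectrum")
    return tuple(name for name, mz in OXONIUM_MZ.items()
                 if _has_peak(s, mz, tol_mz))


def detect_y1(s: Spectrum, p: Peptide | str, tol_mz: float = 0.02,
              charges: Sequence[int] = (1, 2)) -> bool:
    """True iff the peptide+GlcNAc (Y1) ion is present at any tested
    charge."""
    if s.ms_level != 2:
        raise ValueError("Y1 detection needs an MS2 spectrum")
    neutral = peptide_mass(p) + _HEXNAC
    return any(_has_peak(s, (neutral + z * PROTON_MASS) / z, tol_mz)
               for z in charges)


def backbone_ions(p: Peptide | str) -> np.ndarray:
    """Theoretical singly-charged y and b fragment m/z of the naked
    (glycan-free) backbone, fixed modifications included."""
    if isinstance(p, str):
        p = Peptide(p)
    seq = p.sequence
    if len(seq) < 2:
        return np.array([])
    mods = dict(p.fixed_mods)
    res = np.array([
        _pmass.calculate_mass(sequence=aa) - _WATER + mods.get(aa, 0.0)
        for aa in seq
    ])
    prefix = np.cumsum(res)
    b = prefix[:-1] + PROTON_MASS
    y = (prefix[-1] - prefix[:-1]) + _WATER + PROTON_MASS
    return np.concatenate([b, y])


def match_backbone(s: Spectrum, p: Peptide | str, tol_mz: float = 0.02
                   ) -> float:
    """Fraction of theoretical y/b backbone ions found in the spectrum."""
    if s.ms_level != 2:
        raise ValueError("backbone matching needs an MS2 spectrum")
    theo = backbone_ions(p)
    if len(theo) == 0:
        import warnings
        warnings.warn("peptide too short for backbone fragments",
                      stacklevel=2)
        return 0.0
    hits = sum(_has_peak(s, mz, tol_mz) for mz in theo)
    return hits / len(theo)


def _y_ladder(gp: Glycopeptide) -> list[float]:
    """Neutral masses of a peptide + partial-glycan (Y-ion) ladder.

    Residues are peeled in biosynthetic order from the peptide outward:
    core GlcNAc2, then hexoses, then remaining HexNAc, dHex, NeuAc. The
    ladder is a diagnostic series, not a structure claim.
    """
    g = gp.glycan
    order = ([_HEXNAC] * min(2, g.hexnac) + [_HEX] * g.hex
             + [_HEXNAC] * max(0, g.hexnac - 2)
             + [_pmass.calculate_mass(RESIDUE_FORMULAS["dhex"])] * g.dhex
             + [_NEUAC] * g.neuac)
    base = peptide_mass(gp.peptide)
    masses, acc = [], base
    for m in order:
        acc += m
        masses.append(acc)
    return masses


def count_peptide_glycan_ions(s: Spectrum, gp: Glycopeptide,
                              tol_mz: float = 0.02,
                              charges: Sequence[int] = (1, 2)) -> int:
    """Number of peptide+partial-glycan ladder ions found in the
    spectrum (any tested charge; each ladder rung counted once)."""
    count = 0
    for neutral in _y_ladder(gp):
        if any(_has_peak(s, (neutral + z * PROTON_MASS) / z, tol_mz)
               for z in charges):
            count += 1
    return count


def validate(gp: Glycopeptide, ms2: Spectrum,
             config: IdentifyConfig = IdentifyConfig(),
             z: int | None = None) -> ValidationResult:
    """Apply the manual-validation criteria to one candidate/spectrum
    pair.

    Accepted iff the precursor is within tolerance, oxonium ions are
    present, and the backbone is evidenced by Y1 or by y/b coverage at or
    above ``backbone_min_coverage``.
    """
    z = z or ms2.precursor_z or 1
    error, mass_ok = match_precursor(ms2.precursor_mz, z, gp,
                                     config.precursor_tol_da)
    oxonium = detect_oxonium(ms2, config.oxonium_tol_mz)
    oxonium_ok = bool(oxonium) or not config.require_oxonium
    y1 = detect_y1(ms2, gp.peptide, config.fragment_tol_mz,
                   config.y1_charges)
    coverage = match_backbone(ms2, gp.peptide, config.fragment_tol_mz)
    ladder = count_peptide_glycan_ions(ms2, gp, config.fragment_tol_mz,
                                       config.y1_charges)
    accepted = (mass_ok and oxonium_ok
                and (y1 or coverage >= config.backbone_min_coverage))
    return ValidationResult(
        precursor_error_da=error,
        oxonium_found=bool(oxonium),
        oxonium_matched=oxonium,
        y1_found=y1,
        backbone_coverage=coverage,
        peptide_glycan_ions=ladder,
        accepted=accepted,
    )


def build_library(
    protein: str,
    sites=None,
    glycans: Iterable[GlycanComposition] | None = None,
    max_missed: int = 2,
) -> list[Glycopeptide]:
    """In-silico glycopeptide library: single-sequon peptides crossed
    with a glycan grid (default HexNAc 2-8, Hex 3-12, dHex 0-4,
    NeuAc 0-4, biosynthetically pruned)."""
    if glycans is None:
        glycans = enumerate_compositions(range(2, 9), range(3, 13),
                                         range(0, 5), range(0, 5))
    else:
        glycans = list(glycans)
    backbones = single_sequon_glycopeptides(protein, sites,
                                            max_missed=max_missed)
    return [Glycopeptide(pep, site, g)
            for pep, site in backbones for g in glycans]


def search_run(run: Run, library: Sequence[Glycopeptide],
               config: IdentifyConfig = IdentifyConfig()
               ) -> list[Identification]:
    """Match every MS2 spectrum in ``run`` against the library.

    Candidates within the precursor tolerance are validated; per
    spectrum, accepted candidates win over rejected ones and ties break
    on smallest absolute precursor error. Returns one identification per
    spectrum that had at least one accepted candidate.
    """
    lib_masses = np.array([glycopeptide_mass(gp) for gp in library])
    order = np.argsort(lib_masses)
    sorted_masses = lib_masses[order]

    out = []
    for s in run.ms2():
        if s.precursor_mz is None:
            continue
        charges = ((s.precursor_z,) if s.precursor_z
                   else config.precursor_charges)
        best = None
        for z in charges:
            neutral = z * (s.precursor_mz - PROTON_MASS)
            lo = np.searchsorted(sorted_masses,
                                 neutral - config.precursor_tol_da, "left")
            hi = np.searchsorted(sorted_masses,
                                 neutral + config.precursor_tol_da, "right")
            for idx in order[lo:hi]:
                gp = library[idx]
                res = validate(gp, s, config, z=z)
                key = (res.accepted, -abs(res.precursor_error_da))
                if best is None or key > best[0]:
                    best = (key, Identification(gp, z, s.rt, s.scan, res))
        if best is not None and best[1].result.accepted:
            out.append(best[1])
    return out
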