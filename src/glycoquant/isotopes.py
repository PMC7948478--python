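"""Aggregated isotopolog envelopes for peptides and glycopeptides.

The envelope is the unit-mass-binned (aggregated) isotope distribution:
isotopologs are grouped by neutron-count offset from the monoisotopic
species, not resolved into fine structure. Consecutive isotopologs of a
z-charged ion are then spaced ~1.0033548/z in m/z (the 13C-12C mass
difference), which is the spacing the MS1 extraction stage targets.

Per element, the distribution of neutron offsets over n identical atoms
is a multinomial; the envelope of a formula is the convolution of its
element distributions. Distributions are truncated to the requested
number of isotopologs during the convolution and renormalized at the
end, so simulated and extracted envelopes are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

from .glycans import GlycanComposition
from .peptides import (CARBAMIDOMETHYL_FORMULA, Glycopeptide, Peptide, WATER)

__all__ = ["IsotopeEnvelope", "C13_C12_SPACING", "formula_of",
           "envelope", "atomic_isotopes"]

#: Inter-isotopolog spacing approximation (13C - 12C mass difference, Da).
C13_C12_SPACING = (_pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0])

_MOD_FORMULAS = {
    round(_pmass.calculate_mass(CARBAMIDOMETHYL_FORMULA), 4):
        CARBAMIDOMETHYL_FORMULA,
}


@dataclass(frozen=True)
class IsotopeEnvelope:
    """First ``n`` aggregated isotopolog abundances of one species.

    ``offsets[k]`` is the mass offset of isotopolog k from the
    monoisotopic peak (k * 1.0033548 Da); ``abundances`` are relative
    abundances renormalized to sum to 1 over the retained peaks.
    """

    offsets: np.ndarray
    abundances: np.ndarray

    @property
    def n(self) -> int:
        return len(self.abundances)

    def mz(self, mono_mz: float, z: int) -> np.ndarray:
        """Isotopolog m/z targets for a ``z``-charged ion at ``mono_mz``."""
        return mono_mz + self.offsets / z


def atomic_isotopes(element: str) -> tuple[np.ndarray, np.ndarray]:
    """(neutron offsets, abundances) of one atom's naturally occurring
    isotopes, offsets counted from the lightest stable isotope."""
    entries = [(num, m, ab) for num, (m, ab) in _pmass.nist_mass[element].items()
               if num != 0 and ab > 0]
    entries.sort()
    base = entries[0][0]
    offsets = np.array([num - base for num, _, _ in entries])
    abund = np.array([ab for _, _, ab in entries])
    return offsets, abund / abund.sum()


def _element_distribution(element: str, count: int, n: int) -> np.ndarray:
    """Aggregated distribution of neutron offsets for ``count`` atoms,
    truncated to offsets 0..n-1, by binary exponentiation of the single
    atom polynomial."""
    offsets, abund = atomic_isotopes(element)
    single = np.zeros(min(int(offsets.max()), n - 1) + 1)
    for off, ab in zip(offsets, abund):
        if off < n:
            single[int(off)] += ab
    result = np.array([1.0])
    power = single
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, power)[:n]
        k >>= 1
        if k:
            power = np.convolve(power, power)[:n]
    return result


def envelope(formula: _pmass.Composition, n: int = 7) -> IsotopeEnvelope:
    """First ``n`` aggregated isotopolog abundances of ``formula``.

    Abundances are renormalized to sum to 1 over the retained peaks,
    matching how a seven-peak extracted envelope is normalized.
    """
    if n < 1:
        raise ValueError("need at least one isotopolog")
    dist = np.array([1.0])
    for element, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for element {element}")
        if count:
            dist = np.convolve(dist, _element_distribution(element, count, n))[:n]
    out = np.zeros(n)
    out[: len(dist)] = dist
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate isotope distribution")
    return IsotopeEnvelope(
        offsets=np.arange(n) * C13_C12_SPACING,
        abundances=out / total,
    )


def formula_of(gp: Glycopeptide | Peptide | str,
               glycan: GlycanComposition | None = None) -> _pmass.Composition:
    """Total elemental formula: residues + water + fixed mods + glycan."""
    if isinstance(gp, Glycopeptide):
        peptide, glycan = gp.peptide, gp.glycan
    elif isinstance(gp, str):
        peptide = Peptide(gp)
    else:
        peptide = gp
    if peptide.sequence:
        total = _pmass.Composition(sequence=peptide.sequence)
    else:
        total = _pmass.Composition(WATER)
    for res, shift in peptide.fixed_mods:
        count = peptide.sequence.count(res)
        if count:
            mod = _MOD_FORMULAS.get(round(shift, 4))
            if mod is None:
                raise ValueError(
                    f"no elemental formula registered for mod shift {shift}"
                )
            total += mod * count
    if glycan is not None:
        total += glycan.formula
    return total
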