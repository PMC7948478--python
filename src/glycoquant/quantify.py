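"""MS1 isotopolog extraction and glycopeptide abundance.

For a validated glycopeptide at charge z the quantifier walks the MS1
scans of a retention-time window and, for each of the first n (default
seven) isotopolog targets mz0 + k*1.0033548/z, takes the most intense
peak within +/-tol (default 0.015 m/z) per scan — the most-intense rule
resists chimeric neighbours — and sums across scans. The glycopeptide
abundance is the sum of the n isotopolog intensities; abundances of the
same site/glycan are later summed across peptides and charge states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glycans import GlycanComposition
from .isotopes import C13_C12_SPACING
from .peptides import Glycopeptide, glycopeptide_mz
from .spectra import Run

__all__ = ["QuantRecord", "extract_isotopologs", "quantify_glycopeptide"]


@dataclass(frozen=True)
class QuantRecord:
    """Summed isotopolog intensities for one glycopeptide/charge."""

    glycopeptide: Glycopeptide
    z: int
    rt_window: tuple[float, float]
    iso_intensities: tuple[float, ...]
    scans_used: int
    sample: str = ""

    @property
    def abundance(self) -> float:
        return float(sum(self.iso_intensities))

    @property
    def site(self) -> str:
        return self.glycopeptide.site.label

    @property
    def glycan(self) -> GlycanComposition:
        return self.glycopeptide.glycan


def extract_isotopologs(
    run: Run,
    mz0: float,
    z: int,
    rt_window: tuple[float, float],
    n: int = 7,
    tol_mz: float = 0.015,
) -> tuple[np.ndarray, int]:
    """Summed intensities of the first ``n`` isotopolog peaks.

    Per MS1 scan in ``rt_window`` and per target, the single most
    intense peak within ``tol_mz`` contributes; scans and missing peaks
    contribute zero. Returns (intensities, number of scans used).
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    targets = mz0 + np.arange(n) * C13_C12_SPACING / z
    scans = run.rt_slice(*rt_window, ms_level=1)
    if not scans:
        warnings.warn(
            f"no MS1 scans in rt window {rt_window}; intensities are zero",
            stacklevel=2,
        )
        return np.zeros(n), 0
    out = np.zeros(n)
    for s in scans:
        lo = np.searchsorted(s.mz, targets - tol_mz, side="left")
        hi = np.searchsorted(s.mz, targets + tol_mz, side="right")
        for k in range(n):
            if hi[k] > lo[k]:
                out[k] += s.intensity[lo[k]:hi[k]].max()
    return out, len(scans)


def quantify_glycopeptide(
    run: Run,
    gp: Glycopeptide,
    z: int,
    rt_window: tuple[float, float],
    n: int = 7,
    tol_mz: float = 0.015,
) -> QuantRecord:
    """Quantify one validated glycopeptide at one charge state."""
    mz0, _ = glycopeptide_mz(gp, z)
    intensities, scans = extract_isotopologs(run, mz0, z, rt_window, n,
                                             tol_mz)
    return QuantRecord(
        glycopeptide=gp,
        z=z,
        rt_window=rt_window,
        iso_intensities=tuple(float(v) for v in intensities),
        scans_used=scans,
        sample=run.sample,
    )
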