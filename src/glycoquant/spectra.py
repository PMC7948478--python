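"""In-memory model and readers/writers for centroided spectra.

Two interchange formats are supported behind one interface:

* MGF (``BEGIN IONS`` blocks, read and written through :mod:`pyteomics.mgf`)
  with ``RTINSECONDS``, ``PEPMASS``/``CHARGE`` for MS2 precursors and an
  ``MSLEVEL`` parameter so MS1 survey scans can travel in the same file;
* a peak-list TSV dialect with columns
  ``scan, rt_min, ms_level, mz, intensity[, precursor_mz, precursor_z]``,
  one row per peak.

Only centroided data are modeled: peaks are (m/z, intensity) pairs,
sorted ascending in m/z with exact-duplicate m/z merged on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "Run", "read_run", "write_run"]


@dataclass
class Spectrum:
    """One centroided scan."""

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_z: int | None = None
    scan: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")
        self._normalize()

    def _normalize(self) -> None:
        """Sort by m/z and merge exact-duplicate centroids (summing)."""
        order = np.argsort(self.mz, kind="stable")
        mz, inten = self.mz[order], self.intensity[order]
        if len(mz) > 1 and np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            merged = np.zeros_like(uniq)
            np.add.at(merged, inverse, inten)
            mz, inten = uniq, merged
        self.mz, self.intensity = mz, inten

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Run:
    """An LC-MS run: spectra ordered by retention time."""

    spectra: list[Spectrum] = field(default_factory=list)
    sample: str = ""

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: (s.rt, s.scan))
        for i, s in enumerate(self.spectra, start=1):
            if s.scan == 0:
                s.scan = i

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def rt_slice(self, rt_start: float, rt_end: float, ms_level: int = 1
                 ) -> list[Spectrum]:
        return [s for s in self.spectra
                if s.ms_level == ms_level and rt_start <= s.rt <= rt_end]

    def __len__(self) -> int:
        return len(self.spectra)


_TSV_COLUMNS = ["scan", "rt_min", "ms_level", "mz", "intensity",
                "precursor_mz", "precursor_z"]


def _read_tsv(path: Path) -> Run:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path}: empty peak list", stacklevel=3)
        return Run([], sample=path.stem)
    missing = {"scan", "rt_min", "ms_level", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra = []
    for (scan, rt, level), grp in df.groupby(["scan", "rt_min", "ms_level"],
                                             sort=False):
        pmz = pz = None
        if int(level) == 2:
            pmz = float(grp["precursor_mz"].iloc[0])
            pz_val = grp.get("precursor_z")
            if pz_val is not None and pd.notna(pz_val.iloc[0]):
                pz = int(pz_val.iloc[0])
        spectra.append(Spectrum(
            ms_level=int(level), rt=float(rt),
            mz=grp["mz"].to_numpy(), intensity=grp["intensity"].to_numpy(),
            precursor_mz=pmz, precursor_z=pz, scan=int(scan),
        ))
    return Run(spectra, sample=path.stem)


def _write_tsv(run: Run, path: Path) -> None:
    rows = []
    for s in run.spectra:
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((s.scan, s.rt, s.ms_level, mz, inten,
                         s.precursor_mz, s.precursor_z))
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _read_mgf(path: Path) -> Run:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader, start=1):
            params = entry["params"]
            level = int(params.get("mslevel", 2))
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            pmz = pz = None
            if level == 2:
                pep = params.get("pepmass")
                pmz = float(pep[0]) if pep is not None else None
                charges = params.get("charge")
                if charges:
                    pz = int(charges[0])
            spectra.append(Spectrum(
                ms_level=level, rt=rt,
                mz=entry["m/z array"], intensity=entry["intensity array"],
                precursor_mz=pmz, precursor_z=pz,
                scan=int(params.get("scans", i)),
            ))
    if not spectra:
        warnings.warn(f"{path}: empty MGF", stacklevel=3)
    return Run(spectra, sample=path.stem)


def _write_mgf(run: Run, path: Path) -> None:
    entries = []
    for s in run.spectra:
        params: dict = {
            "title": f"scan={s.scan}",
            "scans": s.scan,
            "mslevel": s.ms_level,
            "rtinseconds": round(s.rt * 60.0, 6),
        }
        if s.ms_level == 2:
            params["pepmass"] = s.precursor_mz
            if s.precursor_z:
                params["charge"] = s.precursor_z
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": params,
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_run(path: str | Path, format: str | None = None) -> Run:
    """Load a run; ``format`` is ``"mgf"`` or ``"tsv"`` (default: by
    file suffix). MS1-only files are allowed."""
    path = Path(path)
    fmt = format or ("mgf" if path.suffix.lower() == ".mgf" else "tsv")
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt in ("tsv", "peaklist-tsv"):
        return _read_tsv(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_run(run: Run, path: str | Path, format: str | None = None) -> Path:
    """Write a run so that :func:`read_run` reproduces it (up to float
    formatting, 1e-6 relative)."""
    path = Path(path)
    fmt = format or ("mgf" if path.suffix.lower() == ".mgf" else "tsv")
    if fmt == "mgf":
        _write_mgf(run, path)
    elif fmt in ("tsv", "peaklist-tsv"):
        _write_tsv(run, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
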