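"""Ground-truth LC-MS and qPCR simulators.

Every downstream stage is exercised against data whose truth is known
exactly. The simulator emits centroided MS1 scans carrying glycopeptide
isotopolog envelopes (computed by the same aggregated-isotope model the
extractor assumes, scaled by a truncated-Gaussian elution profile),
decoy peaks uniform in m/z, and MS2 spectra with the diagnostic ion
classes planted at theoretical m/z; and Ct tables consistent with an
exact 2^-ΔΔCt inversion plus Gaussian noise. All randomness flows from
one explicit seed.

``DEMO_PROTEIN`` is a synthetic 200-residue construct (not a natural
sequence) laid out like the five-site Fc γ receptor IIIa extracellular
region it emulates: sequons at positions 38, 45, 74, 162 and 169, with
chymotryptic/Glu-C cleavage sites placed so that each sequon falls on a
fully cleaved peptide containing exactly one sequon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CtTable, DEFAULT_HOUSEKEEPING
from .glycans import GlycanComposition
from .identify import OXONIUM_MZ
from .isotopes import C13_C12_SPACING, envelope, formula_of
from .peptides import (PROTON_MASS, Glycopeptide, Peptide,
                       glycopeptide_mass, peptide_mass,
                       single_sequon_glycopeptides)
from .identify import backbone_ions
from .quantify import QuantRecord
from .spectra import Run, Spectrum

__all__ = [
    "DEMO_PROTEIN", "DEMO_SITE_LABELS", "NoiseModel", "GroundTruth",
    "default_scenario", "simulate_run", "simulate_ms2", "simulate_ct",
]

#: Synthetic five-sequon construct (see module docstring).
DEMO_PROTEIN = (
    "AGSVQDKFHRAGTVKQALSVQDKIHRAETVKQAGYVQNVTHEAGNGSQAGSLQDKIHRAF"
    "TVKQAGSVQWKIHNATTVEQAGSVQDKLHRAGTVKQAYSVQDKIHRAETVKQAGSVQFKI"
    "HRAGTVKLAGSVQDKIHEAGTVKQAGSYQDKIHRAGLVKQANQTEDKINISGTVFQAGSV"
    "QDLIHRAGTVEQAGSVQDWI"
)

DEMO_SITE_LABELS = {38: "N38", 45: "N45", 74: "N74", 162: "N162",
                    169: "N169"}

_HEXNAC_MASS = 203.079373


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise parameters of the simulator.

    ``mz_jitter_sd`` (Da) stays below the 0.015 extraction window;
    ``intensity_cv`` is the coefficient of variation of multiplicative
    (lognormal) intensity noise; decoys are chemical-noise peaks
    uniform over the MS1 scan range.
    """

    mz_jitter_sd: float = 0.003
    intensity_cv: float = 0.05
    decoy_peaks_per_scan: int = 20
    decoy_intensity_mean: float = 2e3

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0, 0.0)


@dataclass
class GroundTruth:
    """True per-site glycoform profiles plus acquisition parameters."""

    sample: str
    site_profiles: dict[str, dict[GlycanComposition, float]]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    site_total_intensity: float = 1.0e7
    charges: tuple[int, ...] = (2, 3)
    rt_start: float = 10.0
    rt_spacing: float = 1.0  # min between glycopeptide apexes
    rt_half_width: float = 0.4  # quantification window half-width
    elution_sd: float = 0.15  # min, truncated-Gaussian elution
    scan_interval: float = 0.1  # min between MS1 scans
    scan_range: tuple[float, float] = (600.0, 2500.0)
    n_isotopologs: int = 7

    def __post_init__(self) -> None:
        for site, prof in self.site_profiles.items():
            total = sum(prof.values())
            if not prof or abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"site {site}: fractions must sum to 1, got {total}")
            if any(f < 0 for f in prof.values()):
                raise ValueError(f"site {site}: negative fraction")


def default_scenario(
    sample: str = "synthetic",
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Five-site scenario with 10 glycoforms per site.

    The profiles qualitatively mirror the biology the pipeline is built
    for: a mixed site (~40% oligomannose / ~10% hybrid / ~50% complex),
    a hybrid-dominated site, a processed sialylated/fucosylated complex
    site, a variable site, and a site carrying truncated forms — so all
    four classifier branches carry signal.
    """
    G = GlycanComposition
    profiles = {
        "N38": {  # mixed, like a partially processed site
            G(2, 5, 0, 0): 0.16, G(2, 6, 0, 0): 0.12, G(2, 7, 0, 0): 0.08,
            G(2, 8, 0, 0): 0.04, G(3, 6, 0, 0): 0.06, G(3, 5, 0, 1): 0.04,
            G(4, 5, 0, 0): 0.14, G(4, 5, 1, 0): 0.14, G(4, 5, 1, 1): 0.12,
            G(4, 5, 1, 2): 0.10,
        },
        "N45": {  # hybrid-dominated
            G(3, 5, 0, 0): 0.18, G(3, 6, 0, 0): 0.16, G(3, 7, 0, 0): 0.12,
            G(3, 6, 0, 1): 0.10, G(2, 5, 1, 0): 0.06, G(3, 7, 0, 1): 0.04,
            G(2, 5, 0, 0): 0.10, G(2, 6, 0, 0): 0.06, G(4, 4, 1, 0): 0.10,
            G(4, 5, 0, 1): 0.08,
        },
        "N74": {  # heavily processed complex, sialylated/fucosylated
            G(4, 5, 0, 1): 0.14, G(4, 5, 1, 2): 0.18, G(5, 6, 0, 2): 0.14,
            G(5, 6, 1, 2): 0.12, G(6, 7, 1, 3): 0.08, G(4, 5, 1, 0): 0.10,
            G(5, 6, 1, 0): 0.08, G(2, 5, 0, 0): 0.06, G(2, 6, 0, 0): 0.04,
            G(3, 6, 0, 1): 0.06,
        },
        "N162": {  # variable: hybrid and complex in balance
            G(3, 5, 0, 0): 0.14, G(3, 6, 0, 0): 0.12, G(3, 6, 0, 1): 0.10,
            G(3, 7, 0, 1): 0.06, G(4, 5, 0, 0): 0.12, G(4, 5, 1, 1): 0.12,
            G(4, 4, 0, 1): 0.10, G(5, 6, 1, 1): 0.08, G(2, 5, 0, 0): 0.10,
            G(2, 7, 0, 0): 0.06,
        },
        "N169": {  # complex plus truncated paucimannose forms
            G(2, 3, 0, 0): 0.08, G(2, 4, 0, 0): 0.06, G(2, 3, 1, 0): 0.04,
            G(4, 5, 0, 0): 0.16, G(4, 5, 1, 0): 0.14, G(4, 5, 1, 1): 0.12,
            G(4, 4, 1, 0): 0.12, G(5, 6, 0, 1): 0.10, G(3, 5, 0, 0): 0.10,
            G(2, 5, 0, 0): 0.08,
        },
    }
    return GroundTruth(sample=sample, site_profiles=profiles,
                       noise=noise or NoiseModel(), seed=seed)


def _site_backbones(protein: str, site_labels: Mapping[int, str]
                    ) -> dict[str, Peptide]:
    """Shortest fully cleaved single-sequon peptide per site."""
    pairs = single_sequon_glycopeptides(protein)
    out: dict[str, Peptide] = {}
    for pep, site in pairs:
        if pep.missed_cleavages:
            continue
        label = site_labels.get(site.position, site.label)
        if label not in out or len(pep.sequence) < len(out[label].sequence):
            out[label] = pep
    return out


def _pick_charge(neutral: float, charges: Sequence[int],
                 scan_range: tuple[float, float], index: int) -> int:
    """Alternate through charge states, preferring ones whose precursor
    falls inside the scan range."""
    usable = [z for z in charges
              if scan_range[0] <= (neutral + z * PROTON_MASS) / z
              <= scan_range[1]]
    pool = usable or list(charges)
    return pool[index % len(pool)]


def simulate_run(
    gt: GroundTruth,
    protein: str = DEMO_PROTEIN,
    site_labels: Mapping[int, str] = DEMO_SITE_LABELS,
    with_ms2: bool = True,
) -> tuple[Run, dict[str, pd.DataFrame]]:
    """Simulate one LC-MS run from ground truth.

    Returns the run plus truth tables: ``site_fractions`` (sample, site,
    glycan, fraction) and ``glycopeptides`` (backbone, site, glycan,
    charge, rt apex/window, true intensity, monoisotopic m/z).
    """
    rng = np.random.default_rng(gt.seed)
    from .peptides import find_sequons
    sites = {site_labels.get(s.position, s.label): s
             for s in find_sequons(protein, site_labels)}
    backbones = _site_backbones(protein, site_labels)
    missing = set(gt.site_profiles) - set(backbones)
    if missing:
        raise ValueError(f"no single-sequon backbone for sites {missing}")

    # lay out one apex per glycopeptide on the scan grid
    entries = []
    idx = 0
    for site_label in sorted(gt.site_profiles):
        pep = backbones[site_label]
        for glycan, frac in sorted(gt.site_profiles[site_label].items(),
                                   key=lambda kv: kv[0].as_tuple()):
            gp = Glycopeptide(pep, sites[site_label], glycan)
            neutral = glycopeptide_mass(gp)
            z = _pick_charge(neutral, gt.charges, gt.scan_range, idx)
            apex = gt.rt_start + idx * gt.rt_spacing
            # snap apex onto the scan grid so every window is symmetric
            apex = round(apex / gt.scan_interval) * gt.scan_interval
            entries.append({
                "gp": gp, "z": z, "apex": apex,
                "intensity": gt.site_total_intensity * frac,
                "fraction": frac,
                "mz0": (neutral + z * PROTON_MASS) / z,
                "envelope": envelope(formula_of(gp),
                                     gt.n_isotopologs).abundances,
            })
            idx += 1

    rt_end = max(e["apex"] for e in entries) + gt.rt_half_width
    times = np.arange(gt.rt_start - gt.rt_half_width,
                      rt_end + gt.scan_interval / 2, gt.scan_interval)

    # per-entry elution weights over the scans inside its rt window,
    # normalized so the planted total equals the true intensity exactly
    spectra = []
    scan_no = 0
    for t in times:
        scan_no += 1
        mz_list, int_list = [], []
        for e in entries:
            dt = t - e["apex"]
            if abs(dt) > gt.rt_half_width + 1e-9:
                continue
            w = math.exp(-0.5 * (dt / gt.elution_sd) ** 2)
            if "wsum" not in e:
                offs = np.arange(-round(gt.rt_half_width / gt.scan_interval),
                                 round(gt.rt_half_width / gt.scan_interval) + 1)
                e["wsum"] = float(np.exp(
                    -0.5 * (offs * gt.scan_interval / gt.elution_sd) ** 2
                ).sum())
            scale = e["intensity"] * w / e["wsum"]
            targets = e["mz0"] + np.arange(gt.n_isotopologs) \
                * C13_C12_SPACING / e["z"]
            inten = scale * e["envelope"]
            if gt.noise.mz_jitter_sd > 0:
                targets = targets + rng.normal(
                    0.0, gt.noise.mz_jitter_sd, len(targets))
            if gt.noise.intensity_cv > 0:
                inten = inten * rng.lognormal(
                    0.0, gt.noise.intensity_cv, len(inten))
            mz_list.append(targets)
            int_list.append(inten)
        if gt.noise.decoy_peaks_per_scan > 0:
            nd = gt.noise.decoy_peaks_per_scan
            mz_list.append(rng.uniform(*gt.scan_range, nd))
            int_list.append(rng.exponential(
                gt.noise.decoy_intensity_mean, nd))
        if not mz_list:
            mz_list, int_list = [np.array([])], [np.array([])]
        mz = np.concatenate(mz_list)
        inten = np.concatenate(int_list)
        keep = mz > 0
        spectra.append(Spectrum(ms_level=1, rt=float(t), mz=mz[keep],
                                intensity=inten[keep], scan=scan_no))

    if with_ms2:
        for e in entries:
            scan_no += 1
            jitter = (rng.normal(0.0, gt.noise.mz_jitter_sd / e["z"])
                      if gt.noise.mz_jitter_sd > 0 else 0.0)
            s = simulate_ms2(e["gp"], z=e["z"], rt=e["apex"],
                             precursor_mz=e["mz0"] + jitter, scan=scan_no)
            spectra.append(s)

    run = Run(spectra, sample=gt.sample)

    site_rows = [
        {"sample": gt.sample, "site": site, "glycan": str(g), "fraction": f}
        for site in sorted(gt.site_profiles)
        for g, f in sorted(gt.site_profiles[site].items(),
                           key=lambda kv: kv[0].as_tuple())
    ]
    gp_rows = [{
        "sample": gt.sample,
        "site": e["gp"].site.label,
        "peptide": e["gp"].peptide.sequence,
        "glycan": str(e["gp"].glycan),
        "z": e["z"],
        "rt_apex": e["apex"],
        # widen by half a scan interval so edge scans are kept despite
        # float rounding of the rt grid
        "rt_start": e["apex"] - gt.rt_half_width - gt.scan_interval / 2,
        "rt_end": e["apex"] + gt.rt_half_width + gt.scan_interval / 2,
        "mz0": e["mz0"],
        "true_intensity": e["intensity"],
        "true_fraction": e["fraction"],
    } for e in entries]
    truth = {
        "site_fractions": pd.DataFrame(site_rows),
        "glycopeptides": pd.DataFrame(gp_rows),
    }
    return run, truth


def simulate_ms2(
    gp: Glycopeptide,
    z: int = 2,
    rt: float = 0.0,
    precursor_mz: float | None = None,
    features: Sequence[str] = ("oxonium", "y1", "backbone", "ladder"),
    scan: int = 0,
    base_intensity: float = 1e4,
) -> Spectrum:
    """MS2 spectrum with the requested diagnostic ion classes planted at
    theoretical m/z.

    ``features`` may contain ``oxonium``, ``y1`` (peptide+GlcNAc),
    ``backbone`` (singly charged y/b ions) and ``ladder``
    (peptide+partial-glycan Y ions).
    """
    if precursor_mz is None:
        precursor_mz = (glycopeptide_mass(gp) + z * PROTON_MASS) / z
    mz, inten = [], []
    if "oxonium" in features:
        for v in OXONIUM_MZ.values():
            mz.append(v)
            inten.append(5 * base_intensity)
    pep_neutral = peptide_mass(gp.peptide)
    if "y1" in features:
        mz.append(pep_neutral + _HEXNAC_MASS + PROTON_MASS)
        inten.append(3 * base_intensity)
    if "backbone" in features:
        for v in backbone_ions(gp.peptide):
            mz.append(float(v))
            inten.append(base_intensity)
    if "ladder" in features:
        from .identify import _y_ladder
        for neutral in _y_ladder(gp):
            mz.append(neutral + PROTON_MASS)
            inten.append(2 * base_intensity)
    if not mz:  # keep the spectrum non-empty but uninformative
        mz, inten = [precursor_mz], [base_intensity]
    return Spectrum(ms_level=2, rt=rt, mz=np.array(mz),
                    intensity=np.array(inten),
                    precursor_mz=precursor_mz, precursor_z=z, scan=scan)


def simulate_ct(
    fold_changes: Mapping[str, float],
    n_replicates: int = 4,
    sigma: float = 0.1,
    seed: int = 0,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    test_group: str = "cell_line",
    reference_group: str = "primary",
) -> CtTable:
    """Ct table whose exact 2^-ΔΔCt inversion recovers ``fold_changes``.

    Reference-group Ct values are drawn per gene from a realistic
    baseline (housekeeping 18-20 cycles, targets 20-28); the test group
    shifts each target gene by -log2(fold change). Gaussian noise with
    SD ``sigma`` cycles is added everywhere, so the recovered log2 fold
    change deviates from truth with SD ~ sigma * sqrt(4/n) (four noisy
    group means enter ΔΔCt).
    """
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    genes = list(housekeeping) + [g for g in fold_changes
                                  if g not in housekeeping]
    baseline = {}
    for g in genes:
        lo, hi = (18.0, 20.0) if g in housekeeping else (20.0, 28.0)
        baseline[g] = rng.uniform(lo, hi)

    samples, groups, cols = [], {}, {}
    for group, tag in ((reference_group, "ref"), (test_group, "test")):
        for i in range(n_replicates):
            name = f"{tag}_{i + 1}"
            samples.append(name)
            groups[name] = group
            col = {}
            for g in genes:
                ct = baseline[g]
                if (group == test_group and g in fold_changes
                        and g not in housekeeping):
                    ct -= math.log2(fold_changes[g])
                if sigma > 0:
                    ct += rng.normal(0.0, sigma)
                col[g] = ct
            cols[name] = col
    values = pd.DataFrame(cols, index=genes, columns=samples)
    return CtTable(values=values, groups=groups, housekeeping=housekeeping)
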