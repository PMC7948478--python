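"""End-to-end orchestration and the pipeline configuration object.

A single :class:`PipelineConfig` carries every tolerance and rule the
stages use, defaults matching the acquisition/extraction conventions the
pipeline is built around (0.015 m/z peak-selection window, seven
isotopologs, chymotrypsin+Glu-C specificity). The effective config is
serialized into every report bundle so no threshold is hidden.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .glycans import GlycanComposition, enumerate_compositions
from .identify import Identification, IdentifyConfig, build_library, search_run
from .peptides import find_sequons
from .profile import (SiteProfile, aggregate_site, profiles_to_frame,
                      summarize)
from .quantify import QuantRecord, quantify_glycopeptide
from .spectra import Run

__all__ = ["PipelineConfig", "run_pipeline", "quant_records_to_frame"]


@dataclass
class PipelineConfig:
    """All tunables of the identification/quantification pipeline."""

    # identification
    precursor_tol_da: float = 0.015
    oxonium_tol_mz: float = 0.02
    fragment_tol_mz: float = 0.02
    backbone_min_coverage: float = 0.25
    y1_charges: tuple[int, ...] = (1, 2)
    precursor_charges: tuple[int, ...] = (2, 3, 4)
    # digestion
    specificity: str = "FWYLE"  # chymotrypsin F/W/Y/L + Glu-C E
    max_missed: int = 2
    # glycan search grid (inclusive bounds)
    hexnac_range: tuple[int, int] = (2, 8)
    hex_range: tuple[int, int] = (3, 12)
    dhex_range: tuple[int, int] = (0, 4)
    neuac_range: tuple[int, int] = (0, 4)
    # quantification
    quant_tol_mz: float = 0.015
    n_isotopologs: int = 7
    rt_half_width: float = 0.5
    # site labels: 1-based sequence position -> reported name
    site_labels: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    def identify_config(self) -> IdentifyConfig:
        return IdentifyConfig(
            precursor_tol_da=self.precursor_tol_da,
            oxonium_tol_mz=self.oxonium_tol_mz,
            fragment_tol_mz=self.fragment_tol_mz,
            backbone_min_coverage=self.backbone_min_coverage,
            y1_charges=tuple(self.y1_charges),
            precursor_charges=tuple(self.precursor_charges),
        )

    def glycan_grid(self) -> list[GlycanComposition]:
        return enumerate_compositions(
            range(self.hexnac_range[0], self.hexnac_range[1] + 1),
            range(self.hex_range[0], self.hex_range[1] + 1),
            range(self.dhex_range[0], self.dhex_range[1] + 1),
            range(self.neuac_range[0], self.neuac_range[1] + 1),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        data = dataclasses.asdict(self)
        for key in ("y1_charges", "precursor_charges", "hexnac_range",
                    "hex_range", "dhex_range", "neuac_range"):
            data[key] = list(data[key])
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("y1_charges", "precursor_charges", "hexnac_range",
                    "hex_range", "dhex_range", "neuac_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "site_labels" in data and data["site_labels"]:
            data["site_labels"] = {int(k): str(v)
                                   for k, v in data["site_labels"].items()}
        return cls(**data)


def quant_records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Quantification TSV layout: one row per glycopeptide x charge."""
    rows = []
    for r in records:
        row = {
            "sample": r.sample,
            "site": r.site,
            "peptide": r.glycopeptide.peptide.sequence,
            "glycan": str(r.glycan),
            "z": r.z,
            "rt_start": r.rt_window[0],
            "rt_end": r.rt_window[1],
        }
        for k, v in enumerate(r.iso_intensities, start=1):
            row[f"iso{k}"] = v
        row["abundance"] = r.abundance
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    run: Run,
    protein: str,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Identify, quantify and profile one run against one protein.

    Returns a bundle with keys ``identifications``, ``quant_records``,
    ``profiles``, ``quant_table``, ``site_table``, ``summary_table``;
    when ``out_dir`` is given, the tables and the effective config are
    also written there as TSV/YAML.
    """
    sites = find_sequons(protein, config.site_labels)
    library = build_library(protein, sites, config.glycan_grid(),
                            config.max_missed)
    idents = search_run(run, library, config.identify_config())
    if not idents:
        warnings.warn("no glycopeptides identified", stacklevel=2)

    # one quantification per (glycopeptide, charge), at the rt of its
    # best-scoring identification
    best: dict[tuple, Identification] = {}
    for ident in idents:
        key = (ident.glycopeptide, ident.z)
        if (key not in best
                or abs(ident.result.precursor_error_da)
                < abs(best[key].result.precursor_error_da)):
            best[key] = ident
    records = [
        quantify_glycopeptide(
            run, ident.glycopeptide, ident.z,
            (ident.rt - config.rt_half_width,
             ident.rt + config.rt_half_width),
            n=config.n_isotopologs, tol_mz=config.quant_tol_mz,
        )
        for ident in best.values()
    ]
    profiles = aggregate_site(records)
    bundle = {
        "identifications": idents,
        "quant_records": records,
        "profiles": profiles,
        "quant_table": quant_records_to_frame(records),
        "site_table": profiles_to_frame(profiles),
        "summary_table": summarize((i, run.sample) for i in idents),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["quant_table"].to_csv(out / "quantification.tsv", sep="\t",
                                     index=False)
        bundle["site_table"].to_csv(out / "site_profiles.tsv", sep="\t",
                                    index=False)
        bundle["summary_table"].to_csv(out / "summary.tsv", sep="\t",
                                       index=False)
        config.to_yaml(out / "effective_config.yaml")
    return bundle
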