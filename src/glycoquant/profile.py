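"""Site-level aggregation: glycoform fractions, type fractions, summaries.

Abundances of identical glycan compositions observed on different
peptides (or charge states) covering the same site are summed; fractions
are computed within one (sample, site) pair, never across sites. A site
with no accepted glycopeptides is "n.d." — an explicit missing profile,
not a row of zeros.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glycans import (GLYCAN_CLASSES, ClassRule, DEFAULT_CLASS_RULES,
                      GlycanComposition, classify_glycan,
                      format_composition)
from .identify import Identification
from .quantify import QuantRecord

__all__ = ["SiteProfile", "aggregate_site", "top_k", "summarize",
           "profiles_to_frame", "plot_class_fractions"]


@dataclass
class SiteProfile:
    """Glycoform abundances and derived fractions for one site."""

    sample: str
    site: str
    abundances: dict[GlycanComposition, float]
    rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    @property
    def detected(self) -> bool:
        """False for an "n.d." site (zero total signal)."""
        return self.total > 0

    @property
    def fractions(self) -> dict[GlycanComposition, float]:
        if not self.detected:
            return {}
        t = self.total
        return {g: a / t for g, a in self.abundances.items()}

    @property
    def class_fractions(self) -> dict[str, float]:
        """Fraction of site signal per maturity class; empty if n.d."""
        if not self.detected:
            return {}
        out = dict.fromkeys(GLYCAN_CLASSES, 0.0)
        for g, f in self.fractions.items():
            out[classify_glycan(g, self.rules)] += f
        return out


def aggregate_site(
    records: Iterable[QuantRecord],
    rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES,
) -> dict[str, SiteProfile]:
    """Per-site profiles from quantification records of one sample.

    Identical compositions at the same site are summed across peptides
    and charge states.
    """
    records = list(records)
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError(f"records span several samples: {sorted(samples)}")
    sample = samples.pop() if samples else ""
    acc: dict[str, dict[GlycanComposition, float]] = defaultdict(
        lambda: defaultdict(float))
    for r in records:
        acc[r.site][r.glycan] += r.abundance
    return {site: SiteProfile(sample, site, dict(gmap), rules)
            for site, gmap in acc.items()}


def top_k(p: SiteProfile, k: int = 10
          ) -> list[tuple[GlycanComposition, float]]:
    """The ``k`` highest-fraction glycoforms; ties break on the
    (HexNAc, Hex, dHex, NeuAc) lexicographic order."""
    ranked = sorted(p.fractions.items(),
                    key=lambda kv: (-kv[1], kv[0].as_tuple()))
    return ranked[:k]


def summarize(
    accepted: Iterable[tuple[Identification, str]],
) -> pd.DataFrame:
    """Identification summary: distinct glycopeptides per site x sample
    and mass-error statistics.

    ``accepted`` yields (identification, sample) pairs. A glycopeptide
    is a (peptide sequence, site, glycan) triple; charge states and
    repeat spectra of one triple count once, and the mass error of each
    distinct triple is its smallest observed absolute error. The
    returned frame has one row per site x sample plus ``_total`` rows,
    and columns n_glycopeptides, n_glycans, mean_abs_error_da,
    sd_abs_error_da.
    """
    best: dict[tuple[str, str, str, GlycanComposition], float] = {}
    for ident, sample in accepted:
        gp = ident.glycopeptide
        key = (sample, gp.site.label, gp.peptide.sequence, gp.glycan)
        err = abs(ident.result.precursor_error_da)
        if key not in best or err < best[key]:
            best[key] = err

    rows = []
    groups: dict[tuple[str, str], list] = defaultdict(list)
    for (sample, site, seq, glycan), err in best.items():
        groups[(sample, site)].append((seq, glycan, err))
    for (sample, site), items in sorted(groups.items()):
        errs = np.array([e for _, _, e in items])
        rows.append({
            "sample": sample, "site": site,
            "n_glycopeptides": len(items),
            "n_glycans": len({g for _, g, _ in items}),
            "mean_abs_error_da": errs.mean(),
            "sd_abs_error_da": errs.std(ddof=1) if len(errs) > 1 else 0.0,
        })
    # per-sample and overall totals with set semantics for glycan counts
    by_sample: dict[str, list] = defaultdict(list)
    for (sample, site, seq, glycan), err in best.items():
        by_sample[sample].append((site, seq, glycan, err))
    for sample, items in sorted(by_sample.items()):
        errs = np.array([e for *_, e in items])
        rows.append({
            "sample": sample, "site": "_total",
            "n_glycopeptides": len(items),
            "n_glycans": len({g for _, _, g, _ in items}),
            "mean_abs_error_da": errs.mean(),
            "sd_abs_error_da": errs.std(ddof=1) if len(errs) > 1 else 0.0,
        })
    if best:
        errs = np.array(list(best.values()))
        rows.append({
            "sample": "_all", "site": "_total",
            "n_glycopeptides": len(best),
            "n_glycans": len({g for (_, _, _, g) in best}),
            "mean_abs_error_da": errs.mean(),
            "sd_abs_error_da": errs.std(ddof=1) if len(errs) > 1 else 0.0,
        })
    return pd.DataFrame(
        rows, columns=["sample", "site", "n_glycopeptides", "n_glycans",
                       "mean_abs_error_da", "sd_abs_error_da"])


def profiles_to_frame(profiles: Mapping[str, SiteProfile]) -> pd.DataFrame:
    """Long-format site/glycan/fraction table (columns sample, site,
    glycan in four-number notation, abundance, fraction, glycan_class).
    n.d. sites appear once with NaN fraction."""
    rows = []
    for site, p in sorted(profiles.items()):
        if not p.detected:
            rows.append({"sample": p.sample, "site": site, "glycan": "n.d.",
                         "abundance": 0.0, "fraction": np.nan,
                         "glycan_class": "n.d."})
            continue
        for g, a in sorted(p.abundances.items(), key=lambda kv: kv[0].as_tuple()):
            rows.append({
                "sample": p.sample, "site": site,
                "glycan": format_composition(g),
                "abundance": a,
                "fraction": a / p.total,
                "glycan_class": classify_glycan(g, p.rules),
            })
    return pd.DataFrame(rows, columns=["sample", "site", "glycan",
                                       "abundance", "fraction",
                                       "glycan_class"])


def plot_class_fractions(profiles: Mapping[str, SiteProfile], ax=None):
    """Stacked bar chart of glycan-type fractions per site."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(profiles), 2), 3.2))
    sites = sorted(profiles)
    bottom = np.zeros(len(sites))
    for cls in GLYCAN_CLASSES:
        vals = np.array([profiles[s].class_fractions.get(cls, 0.0)
                         for s in sites])
        ax.bar(sites, vals, bottom=bottom, label=cls)
        bottom += vals
    ax.set_ylabel("fraction of site signal")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax
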