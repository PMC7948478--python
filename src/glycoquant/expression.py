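"""qRT-PCR fold changes (2^-ΔΔCt) and cross-method concordance.

Ct values are normalized per sample to the arithmetic mean of a
housekeeping panel (default ACTB, B2M, GAPDH, RPLP0, HPRT1), contrasted
between a test and a reference group, and exponentiated to linear fold
changes. Concordance between qPCR and RNA-Seq fold changes is the
squared Pearson correlation of log2 fold changes by default — on the
log scale one extreme fold change cannot dominate the fit, so an
influential outlier shows up in the leave-one-out profile instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CtTable", "DEFAULT_HOUSEKEEPING", "ddct_fold_change",
           "logfc_r2", "leave_one_out_r2"]

DEFAULT_HOUSEKEEPING = ("ACTB", "B2M", "GAPDH", "RPLP0", "HPRT1")


@dataclass
class CtTable:
    """Gene x sample cycle-threshold matrix with group labels.

    ``values``: DataFrame indexed by gene, columns are samples.
    ``groups``: sample -> group label. ``housekeeping`` genes must be
    present (finite) in every sample.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        missing_hk = [g for g in self.housekeeping
                      if g not in self.values.index
                      or not np.isfinite(self.values.loc[g]).all()]
        if missing_hk:
            raise ValueError(
                f"housekeeping genes missing or non-finite: {missing_hk}")
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group labels: {sorted(unknown)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def delta_ct(self) -> pd.DataFrame:
        """Per-sample ΔCt: Ct(gene) minus the arithmetic mean Ct of the
        housekeeping panel in that sample."""
        hk_mean = self.values.loc[list(self.housekeeping)].mean(axis=0)
        return self.values.sub(hk_mean, axis=1)


def ddct_fold_change(ct: CtTable, test: str, reference: str
                     ) -> pd.DataFrame:
    """2^-ΔΔCt fold changes of ``test`` relative to ``reference``.

    ΔΔCt = mean ΔCt over test samples − mean ΔCt over reference
    samples; genes absent (non-finite) in the reference group are
    omitted with a warning. Returns a frame indexed by gene with
    columns ``ddct``, ``fold_change`` and ``log2_fold_change``.
    """
    ref_samples = ct.samples_in(reference)
    test_samples = ct.samples_in(test)
    if not ref_samples:
        raise ValueError(f"reference group {reference!r} is empty")
    if not test_samples:
        raise ValueError(f"test group {test!r} is empty")
    dct = ct.delta_ct()
    mean_test = dct[test_samples].mean(axis=1)
    mean_ref = dct[ref_samples].mean(axis=1)
    ddct = mean_test - mean_ref
    bad = ~np.isfinite(ddct)
    if bad.any():
        import warnings
        warnings.warn(
            f"omitting genes without complete Ct values: "
            f"{sorted(ddct.index[bad])}", stacklevel=2)
        ddct = ddct[~bad]
    fc = np.power(2.0, -ddct)
    return pd.DataFrame({
        "ddct": ddct,
        "fold_change": fc,
        "log2_fold_change": -ddct,
    })


def _paired_logfc(fc: pd.DataFrame, method_a: str, method_b: str,
                  log_scale: bool) -> pd.DataFrame:
    pair = fc[[method_a, method_b]].dropna()
    if (pair <= 0).any().any():
        raise ValueError("fold changes must be positive")
    if log_scale:
        pair = np.log2(pair)
    return pair


def logfc_r2(fc: pd.DataFrame, method_a: str = "qpcr",
             method_b: str = "rnaseq", log_scale: bool = True) -> float:
    """Coefficient of determination (squared Pearson r) between the two
    methods' fold changes over shared genes, on log2 scale by default.

    ``fc`` is indexed by gene with one linear-scale fold-change column
    per method. Requires at least 3 shared genes.
    """
    pair = _paired_logfc(fc, method_a, method_b, log_scale)
    if len(pair) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(pair)}")
    r, _ = stats.pearsonr(pair[method_a], pair[method_b])
    return float(r ** 2)


def leave_one_out_r2(fc: pd.DataFrame, method_a: str = "qpcr",
                     method_b: str = "rnaseq", log_scale: bool = True
                     ) -> tuple[pd.Series, str]:
    """R² after dropping each gene in turn; also the most influential
    gene (whose removal raises R² the most). Requires >= 4 shared
    genes so every leave-one-out fit keeps >= 3 points."""
    pair = _paired_logfc(fc, method_a, method_b, log_scale)
    if len(pair) < 4:
        raise ValueError(f"need >= 4 shared genes, got {len(pair)}")
    out = {}
    for gene in pair.index:
        sub = pair.drop(index=gene)
        r, _ = stats.pearsonr(sub[method_a], sub[method_b])
        out[gene] = float(r ** 2)
    series = pd.Series(out, name="r2_without_gene")
    return series, str(series.idxmax())
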