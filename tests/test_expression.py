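import math

import numpy as np
import pandas as pd
import pytest

from glycoquant.expression import (CtTable, DEFAULT_HOUSEKEEPING,
                                   ddct_fold_change, leave_one_out_r2,
                                   logfc_r2)
from glycoquant.synthetic import simulate_ct

HK = list(DEFAULT_HOUSEKEEPING)


def ct_table(gene_ct_test, gene_ct_ref, hk_test=18.0, hk_ref=18.0):
    genes = HK + sorted(gene_ct_test)
    cols = {}
    cols["t1"] = {g: hk_test for g in HK} | gene_ct_test
    cols["r1"] = {g: hk_ref for g in HK} | gene_ct_ref
    values = pd.DataFrame(cols).reindex(genes)
    return CtTable(values, groups={"t1": "test", "r1": "ref"})


def test_ddct_hand_example():
    # ΔCt 2 in test, 4 in reference → ΔΔCt −2 → fold change 4
    ct = ct_table({"MGAT5": 20.0}, {"MGAT5": 22.0})
    fc = ddct_fold_change(ct, "test", "ref")
    assert fc.loc["MGAT5", "ddct"] == pytest.approx(-2.0)
    assert fc.loc["MGAT5", "fold_change"] == pytest.approx(4.0)


def test_ddct_identities():
    ct = ct_table({"A2M": 21.0}, {"A2M": 21.0})
    fc = ddct_fold_change(ct, "test", "ref")
    assert fc.loc["A2M", "fold_change"] == pytest.approx(1.0)  # ΔΔCt 0
    ct2 = ct_table({"A2M": 20.0}, {"A2M": 21.0})
    fc2 = ddct_fold_change(ct2, "test", "ref")
    assert fc2.loc["A2M", "fold_change"] == pytest.approx(2.0)  # ΔΔCt −1


def test_housekeeping_fold_change_is_one():
    ct = ct_table({"X": 20.0}, {"X": 25.0})
    fc = ddct_fold_change(ct, "test", "ref")
    for hk in HK:
        assert fc.loc[hk, "fold_change"] == pytest.approx(1.0)


def test_missing_reference_gene_omitted_with_warning():
    ct = ct_table({"X": 20.0, "Y": 21.0},
                  {"X": 22.0, "Y": float("nan")})
    with pytest.warns(UserWarning):
        fc = ddct_fold_change(ct, "test", "ref")
    assert "Y" not in fc.index
    assert "X" in fc.index


def test_housekeeping_must_be_present():
    values = pd.DataFrame({"s1": {"GENE": 20.0}})
    with pytest.raises(ValueError):
        CtTable(values, groups={"s1": "test"})


def fc_frame(qpcr, rnaseq, genes=None):
    genes = genes or [f"g{i}" for i in range(len(qpcr))]
    return pd.DataFrame({"qpcr": qpcr, "rnaseq": rnaseq}, index=genes)


def test_r2_identities():
    fc = fc_frame([2.0, 4.0, 0.5, 8.0], [2.0, 4.0, 0.5, 8.0])
    assert logfc_r2(fc) == pytest.approx(1.0)
    # y = 2x in log space is still perfectly correlated
    fc2 = fc_frame([2.0, 4.0, 0.5, 8.0], [4.0, 16.0, 0.25, 64.0])
    assert logfc_r2(fc2) == pytest.approx(1.0)


def test_r2_scale_invariance():
    rng = np.random.default_rng(0)
    x = np.exp(rng.normal(0, 1, 12))
    y = x * np.exp(rng.normal(0, 0.3, 12))
    fc = fc_frame(x, y)
    fc_scaled = fc_frame(x * 7.5, y)
    assert logfc_r2(fc) == pytest.approx(logfc_r2(fc_scaled))


def test_r2_matches_independent_correlation_oracle():
    rng = np.random.default_rng(1)
    lx = rng.normal(0, 2, 15)
    ly = 0.8 * lx + rng.normal(0, 0.5, 15)
    fc = fc_frame(np.exp2(lx), np.exp2(ly))
    expected = float(np.corrcoef(lx, ly)[0, 1] ** 2)
    assert logfc_r2(fc) == pytest.approx(expected, abs=1e-12)


def test_r2_requires_three_genes():
    with pytest.raises(ValueError):
        logfc_r2(fc_frame([2.0, 4.0], [2.0, 4.0]))


def test_leave_one_out_flags_planted_outlier():
    rng = np.random.default_rng(2)
    lx = rng.normal(0, 1.5, 9)
    ly = lx + rng.normal(0, 0.2, 9)
    lx = np.append(lx, 0.5)
    ly = np.append(ly, 9.0)  # gross outlier, like one discordant gene
    genes = [f"g{i}" for i in range(9)] + ["OUTLIER"]
    fc = fc_frame(np.exp2(lx), np.exp2(ly), genes)
    base = logfc_r2(fc)
    loo, influential = leave_one_out_r2(fc)
    assert influential == "OUTLIER"
    assert loo["OUTLIER"] > base


def test_leave_one_out_collinear_stays_perfect():
    fc = fc_frame([2.0, 4.0, 0.5, 8.0, 1.0], [2.0, 4.0, 0.5, 8.0, 1.0])
    loo, _ = leave_one_out_r2(fc)
    assert np.allclose(loo.values, 1.0)


def test_simulated_ct_round_trip_noiseless():
    truth = {"MGAT5": 4.0, "FUT7": 0.5, "MAN2A2": 1.0}
    ct = simulate_ct(truth, n_replicates=3, sigma=0.0, seed=0)
    fc = ddct_fold_change(ct, "cell_line", "primary")
    for gene, val in truth.items():
        assert fc.loc[gene, "fold_change"] == pytest.approx(val, rel=1e-12)
    for hk in HK:
        assert fc.loc[hk, "fold_change"] == pytest.approx(1.0, rel=1e-12)


def test_simulated_ct_noisy_recovery_within_sampling_bound():
    truth = {"MGAT5": 4.0, "FUT7": 0.5, "ST6GAL1": 1.0,
             "MAN2A2": 2.0, "B3GNT7": 8.0, "ST3GAL6": 0.25}
    sigma, n = 0.1, 4
    ct = simulate_ct(truth, n_replicates=n, sigma=sigma, seed=0)
    fc = ddct_fold_change(ct, "cell_line", "primary")
    bound = 3 * sigma / math.sqrt(n)
    for gene, val in truth.items():
        dev = abs(fc.loc[gene, "log2_fold_change"] - math.log2(val))
        assert dev <= bound, gene
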