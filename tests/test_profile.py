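import numpy as np
import pytest

from glycoquant.glycans import GlycanComposition
from glycoquant.identify import Identification, ValidationResult
from glycoquant.profile import (SiteProfile, aggregate_site,
                                profiles_to_frame, summarize, top_k)
from glycoquant.quantify import QuantRecord

G = GlycanComposition


def record(make_gp, site, glycan, abundance, z=2, sample="s1"):
    gp = make_gp(site, glycan)
    return QuantRecord(gp, z=z, rt_window=(0., 1.),
                       iso_intensities=(abundance, 0., 0., 0., 0., 0., 0.),
                       scans_used=1, sample=sample)


def ident(make_gp, site, glycan, err, peptide=None):
    gp = make_gp(site, glycan)
    res = ValidationResult(err, True, ("HexNAc",), True, 1.0, 1, True)
    return Identification(gp, 2, 1.0, 1, res)


def test_same_glycan_summed_across_records(make_gp):
    recs = [record(make_gp, "N38", G(2, 5, 0, 0), 3e6),
            record(make_gp, "N38", G(2, 5, 0, 0), 1e6, z=3)]
    prof = aggregate_site(recs)["N38"]
    assert prof.abundances[G(2, 5, 0, 0)] == pytest.approx(4e6)
    assert prof.fractions[G(2, 5, 0, 0)] == pytest.approx(1.0)


def test_class_fractions(make_gp):
    recs = [record(make_gp, "N38", G(2, 5, 0, 0), 1e6),
            record(make_gp, "N38", G(4, 5, 0, 2), 3e6)]
    cf = aggregate_site(recs)["N38"].class_fractions
    assert cf["oligomannose"] == pytest.approx(0.25)
    assert cf["complex"] == pytest.approx(0.75)
    assert sum(cf.values()) == pytest.approx(1.0, abs=1e-9)


def test_aggregation_order_invariant(make_gp):
    recs = [record(make_gp, "N38", G(2, 5, 0, 0), 1e6),
            record(make_gp, "N38", G(4, 5, 0, 2), 3e6),
            record(make_gp, "N45", G(3, 6, 0, 0), 2e6)]
    a = aggregate_site(recs)
    b = aggregate_site(recs[::-1])
    for site in a:
        assert a[site].fractions == b[site].fractions


def test_records_must_share_sample(make_gp):
    recs = [record(make_gp, "N38", G(2, 5, 0, 0), 1e6, sample="a"),
            record(make_gp, "N38", G(2, 5, 0, 0), 1e6, sample="b")]
    with pytest.raises(ValueError):
        aggregate_site(recs)


def test_nd_site_is_missing_not_zero(make_gp):
    recs = [record(make_gp, "N169", G(4, 5, 0, 0), 0.0)]
    prof = aggregate_site(recs)["N169"]
    assert not prof.detected
    assert prof.fractions == {}
    assert prof.class_fractions == {}
    frame = profiles_to_frame({"N169": prof})
    assert frame.loc[0, "glycan"] == "n.d."
    assert np.isnan(frame.loc[0, "fraction"])


def test_top_k_ranking_and_ties():
    prof = SiteProfile("s", "N38", {
        G(4, 5, 0, 2): 3.0, G(2, 5, 0, 0): 3.0, G(3, 6, 0, 0): 4.0,
    })
    ranked = top_k(prof, k=10)
    assert len(ranked) == 3
    assert ranked[0][0] == G(3, 6, 0, 0)
    # tie broken by (HexNAc, Hex, dHex, NeuAc) lexicographic order
    assert [r[0] for r in ranked[1:]] == [G(2, 5, 0, 0), G(4, 5, 0, 2)]
    assert top_k(prof, k=2) == ranked[:2]


def test_summarize_unique_triples(make_gp):
    idents = [
        (ident(make_gp, "N38", G(2, 5, 0, 0), 0.001), "s1"),
        (ident(make_gp, "N38", G(2, 5, 0, 0), 0.003), "s1"),  # duplicate
        (ident(make_gp, "N38", G(4, 5, 0, 2), 0.003), "s1"),
        (ident(make_gp, "N45", G(2, 5, 0, 0), 0.002), "s1"),
        (ident(make_gp, "N45", G(2, 5, 0, 0), 0.002), "s2"),
    ]
    table = summarize(idents)
    n38 = table[(table["sample"] == "s1") & (table["site"] == "N38")].iloc[0]
    assert n38["n_glycopeptides"] == 2
    s1 = table[(table["sample"] == "s1") & (table["site"] == "_total")].iloc[0]
    assert s1["n_glycopeptides"] == 3
    # shared composition counted once overall
    overall = table[(table["sample"] == "_all")].iloc[0]
    assert overall["n_glycans"] == 2
    assert overall["n_glycopeptides"] == 4


def test_summarize_idempotent_under_duplication(make_gp):
    idents = [(ident(make_gp, "N38", G(2, 5, 0, 0), 0.001), "s1"),
              (ident(make_gp, "N74", G(3, 6, 0, 0), 0.004), "s1")]
    once = summarize(idents)
    twice = summarize(idents * 2)
    assert once.equals(twice)


def test_summarize_error_stats(make_gp):
    idents = [(ident(make_gp, "N38", G(2, 5, 0, 0), 0.001), "s1"),
              (ident(make_gp, "N38", G(4, 5, 0, 2), -0.003), "s1")]
    row = summarize(idents)
    n38 = row[(row["site"] == "N38")].iloc[0]
    assert n38["mean_abs_error_da"] == pytest.approx(0.002)
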