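import random

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pparser

from glycoquant.glycans import GlycanComposition
from glycoquant.peptides import (
    CHYMOTRYPSIN, DEFAULT_SPECIFICITY, GLUC, Glycopeptide, Peptide,
    digest, find_sequons, glycopeptide_mz, peptide_mass,
)
from _oracles import digest_oracle

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1,
                    max_size=30)


@pytest.mark.parametrize("protein,positions", [
    ("ANVSA", [2]),
    ("ANPSA", []),          # X = P excluded
    ("NVSNVT", [1, 4]),
    ("ANVA", []),           # no S/T
    ("NST", [1]),
])
def test_find_sequons(protein, positions):
    assert [s.position for s in find_sequons(protein)] == positions


def test_find_sequons_rejects_invalid_letters():
    with pytest.raises(ValueError):
        find_sequons("ANXSA")


@pytest.mark.parametrize("protein,spec,mm,expected", [
    ("AEWGK", frozenset("EW"), 0, {"AE", "W", "GK"}),
    ("AEWGK", frozenset("EW"), 1, {"AE", "W", "GK", "AEW", "WGK"}),
    ("GGGG", DEFAULT_SPECIFICITY, 0, {"GGGG"}),
    ("AEPGK", frozenset("E"), 0, {"AEPGK"}),  # no cleavage before P
])
def test_digest_examples(protein, spec, mm, expected):
    assert {p.sequence for p in digest(protein, spec, mm)} == expected


def test_digest_rejects_empty_sequence():
    with pytest.raises(ValueError):
        digest("", DEFAULT_SPECIFICITY, 0)


@settings(max_examples=60, derandomize=True)
@given(sequences, st.integers(min_value=0, max_value=3))
def test_digest_matches_subset_enumeration(protein, max_missed):
    got = {(p.start, p.end, p.sequence, p.missed_cleavages)
           for p in digest(protein, DEFAULT_SPECIFICITY, max_missed)}
    assert got == digest_oracle(protein, DEFAULT_SPECIFICITY, max_missed)


@settings(max_examples=40, derandomize=True)
@given(sequences)
def test_full_cleavage_reconstructs_protein(protein):
    peps = [p for p in digest(protein, DEFAULT_SPECIFICITY, 0)]
    peps.sort(key=lambda p: p.start)
    assert "".join(p.sequence for p in peps) == protein
    assert all(protein[p.start - 1:p.end] == p.sequence for p in peps)


def test_digest_agrees_with_pyteomics_cleave():
    """Peptide sets match an established digestion routine for the
    combined chymotrypsin+Glu-C specificity."""
    rng = random.Random(3)
    rule = r"(?<=[FWYLE])(?!P)"
    for _ in range(25):
        protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                          for _ in range(rng.randint(1, 40)))
        for mm in (0, 2):
            ours = {p.sequence for p in digest(protein, DEFAULT_SPECIFICITY, mm)}
            ref = set(pparser.cleave(protein, rule, missed_cleavages=mm))
            assert ours == ref


@pytest.mark.parametrize("seq,expected", [
    ("GG", 132.0535),
    ("", 18.0106),       # bare water
    ("C", 178.0412),     # cysteine + carbamidomethyl + water
])
def test_peptide_mass(seq, expected):
    assert peptide_mass(seq) == pytest.approx(expected, abs=5e-4)


def test_glycopeptide_mz_arithmetic():
    mz, ok = glycopeptide_mz(2000.0, 2)
    assert mz == pytest.approx(1001.00728, abs=1e-5)
    assert ok
    mz1, ok1 = glycopeptide_mz(2000.0, 1)
    assert mz1 == pytest.approx(2001.00728, abs=1e-5)
    assert ok1  # within 600-2500
    _, ok_low = glycopeptide_mz(400.0, 1)
    assert not ok_low
    with pytest.raises(ValueError):
        glycopeptide_mz(2000.0, 0)


def test_glycopeptide_requires_single_sequon():
    pep = Peptide("ANVSANVTA", start=1)
    site = find_sequons("ANVSANVTA")[0]
    with pytest.raises(ValueError):
        Glycopeptide(pep, site, GlycanComposition(2, 5, 0, 0))


def test_glycopeptide_site_must_be_covered():
    pep = Peptide("ANVSA", start=10)  # covers 10..14
    with pytest.raises(ValueError):
        Glycopeptide(pep, find_sequons("GANVSA")[0],
                     GlycanComposition(2, 5, 0, 0))
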