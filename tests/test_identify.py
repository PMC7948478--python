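import numpy as np
import pytest

from glycoquant.glycans import GlycanComposition
from glycoquant.identify import (
    IdentifyConfig, OXONIUM_MZ, backbone_ions, build_library,
    detect_oxonium, detect_y1, match_backbone, match_precursor, validate,
)
from glycoquant.peptides import PROTON_MASS, glycopeptide_mass, peptide_mass
from glycoquant.spectra import Spectrum
from glycoquant.synthetic import simulate_ms2

G = GlycanComposition


def ms2(mz, precursor_mz=1000.0, z=2):
    mz = np.asarray(mz, dtype=float)
    return Spectrum(2, rt=0.0, mz=mz, intensity=np.ones_like(mz),
                    precursor_mz=precursor_mz, precursor_z=z)


def test_oxonium_mz_values():
    # canonical diagnostic masses, from the residue elemental formulas
    assert OXONIUM_MZ["HexNAc"] == pytest.approx(204.0867, abs=5e-4)
    assert OXONIUM_MZ["HexHexNAc"] == pytest.approx(366.1395, abs=5e-4)
    assert OXONIUM_MZ["NeuAc"] == pytest.approx(292.1027, abs=5e-4)
    assert OXONIUM_MZ["NeuAc-H2O"] == pytest.approx(274.0921, abs=5e-4)
    assert OXONIUM_MZ["HexNAc-C2H6O3"] == pytest.approx(138.0550, abs=5e-4)


def test_match_precursor_linearity(make_gp):
    gp = make_gp("N38", G(2, 5, 0, 0))
    theo = glycopeptide_mass(gp)
    for z in (2, 3):
        mz_exact = (theo + z * PROTON_MASS) / z
        err, ok = match_precursor(mz_exact, z, gp)
        assert err == pytest.approx(0.0, abs=1e-9)
        assert ok
        err, ok = match_precursor(mz_exact + 0.005 / z, z, gp)
        assert err == pytest.approx(0.005, abs=1e-9)
        assert ok
        err, ok = match_precursor(mz_exact + 0.02 / z, z, gp, tol_da=0.015)
        assert not ok


def test_detect_oxonium():
    assert "HexNAc" in detect_oxonium(ms2([204.087]), tol_mz=0.02)
    assert detect_oxonium(ms2([777.0])) == ()
    assert detect_oxonium(ms2([204.15]), tol_mz=0.02) == ()


def test_detect_y1_charge_states(make_gp):
    gp = make_gp("N45", G(3, 6, 0, 0))
    neutral = peptide_mass(gp.peptide) + 203.079373
    y1_z2 = (neutral + 2 * PROTON_MASS) / 2
    assert detect_y1(ms2([y1_z2]), gp.peptide, charges=(1, 2))
    assert not detect_y1(ms2([y1_z2]), gp.peptide, charges=(1,))
    assert not detect_y1(ms2([500.0]), gp.peptide)


def test_match_backbone_counts_fractions(make_gp):
    gp = make_gp("N74", G(2, 5, 0, 0))
    ions = backbone_ions(gp.peptide)
    assert match_backbone(ms2(ions), gp.peptide) == pytest.approx(1.0)
    assert match_backbone(ms2([50.0]), gp.peptide) == 0.0
    half = ions[: len(ions) // 2]
    assert match_backbone(ms2(half), gp.peptide) == pytest.approx(
        len(half) / len(ions))


def test_short_peptide_backbone_warns():
    from glycoquant.peptides import Peptide
    with pytest.warns(UserWarning):
        assert match_backbone(ms2([100.0]), Peptide("G")) == 0.0


def test_validate_accepts_fully_planted(make_gp):
    gp = make_gp("N38", G(2, 5, 0, 0))
    res = validate(gp, simulate_ms2(gp, z=2))
    assert res.accepted
    assert res.oxonium_found and res.y1_found
    assert res.backbone_coverage == pytest.approx(1.0)
    assert res.peptide_glycan_ions > 0
    assert abs(res.precursor_error_da) < 1e-9


def test_validate_rejects_missing_oxonium(make_gp):
    gp = make_gp("N38", G(2, 5, 0, 0))
    res = validate(gp, simulate_ms2(gp, z=2, features=("y1", "backbone")))
    assert not res.accepted and not res.oxonium_found


def test_validate_rejects_precursor_off_by_30mda(make_gp):
    gp = make_gp("N38", G(2, 5, 0, 0))
    z = 2
    mz = (glycopeptide_mass(gp) + z * PROTON_MASS) / z + 0.03 / z
    res = validate(gp, simulate_ms2(gp, z=z, precursor_mz=mz))
    assert not res.accepted
    assert res.precursor_error_da == pytest.approx(0.03, abs=1e-6)


def test_validate_accepts_via_backbone_without_y1(make_gp):
    gp = make_gp("N38", G(2, 5, 0, 0))
    res = validate(gp, simulate_ms2(gp, z=2, features=("oxonium", "backbone")))
    assert res.accepted and not res.y1_found


def test_acceptance_monotone_in_tolerance(make_gp):
    """Widening the precursor tolerance never un-accepts a candidate."""
    gp = make_gp("N162", G(4, 5, 1, 1))
    z = 2
    mz = (glycopeptide_mass(gp) + z * PROTON_MASS) / z + 0.004
    spec = simulate_ms2(gp, z=z, precursor_mz=mz)
    accepted = [
        validate(gp, spec, IdentifyConfig(precursor_tol_da=tol)).accepted
        for tol in (0.001, 0.005, 0.01, 0.02, 0.05)
    ]
    assert accepted == sorted(accepted)


def test_build_library_single_sequon_only():
    from glycoquant.synthetic import DEMO_PROTEIN
    lib = build_library(DEMO_PROTEIN, glycans=[G(2, 5, 0, 0)])
    assert lib
    labels = {gp.site.label for gp in lib}
    assert len(labels) == 5
    from glycoquant.peptides import find_sequons
    assert all(len(find_sequons(gp.peptide.sequence)) == 1 for gp in lib)
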