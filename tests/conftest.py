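import numpy as np
import pytest

from glycoquant import synthetic
from glycoquant.glycans import GlycanComposition
from glycoquant.peptides import Glycopeptide, single_sequon_glycopeptides


@pytest.fixture(scope="session")
def backbones():
    """Site label -> (peptide, site) for the demo construct's fully
    cleaved single-sequon peptides."""
    out = {}
    for pep, site in single_sequon_glycopeptides(synthetic.DEMO_PROTEIN):
        label = synthetic.DEMO_SITE_LABELS.get(site.position, site.label)
        if pep.missed_cleavages == 0:
            out.setdefault(label, (pep, site))
    return out


@pytest.fixture(scope="session")
def make_gp(backbones):
    def _make(site_label: str, glycan: GlycanComposition) -> Glycopeptide:
        pep, site = backbones[site_label]
        return Glycopeptide(pep, site, glycan)
    return _make


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default five-site, 50-glycoform scenario with the default noise
    model, simulated once per session."""
    gt = synthetic.default_scenario(seed=1)
    run, truth = synthetic.simulate_run(gt)
    return gt, run, truth


@pytest.fixture(scope="session")
def clean_two_form_run():
    """Zero-noise run with two glycoforms at 70/30 on one site."""
    gt = synthetic.GroundTruth(
        sample="clean",
        site_profiles={"N38": {GlycanComposition(2, 5, 0, 0): 0.7,
                               GlycanComposition(4, 5, 1, 2): 0.3}},
        noise=synthetic.NoiseModel.noiseless(),
        seed=0,
    )
    run, truth = synthetic.simulate_run(gt)
    return gt, run, truth
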