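# glycoquant

Site-specific quantification of intact N-glycopeptides from a single
purified glycoprotein, for glycoproteomics studies that ask *which glycan
structures sit on which sequon* — e.g. profiling the five N-glycosylation
sites of the Fc γ receptor IIIa (CD16a) expressed by different cell lines.

## What it computes

Given a protein sequence and centroided LC-MS data, the pipeline:

1. **Digests** the protein in silico (combined chymotrypsin F/W/Y/L +
   Glu-C E specificity, no cleavage before proline, missed cleavages
   allowed) and keeps peptides carrying exactly one N-X-S/T sequon
   (X ≠ P), so each glycoform is attributable to a single site.
2. **Matches** MS2 precursors against a targeted library of
   peptide × glycan-composition candidates, where a glycan composition
   is the residue-count vector (HexNAc, Hex, dHex, NeuAc) and the
   precursor test is |M_obs − M_theo| ≤ 0.015 Da with
   M_obs = z·(m/z − m_p).
3. **Validates** each candidate against its MS2 spectrum: glycan oxonium
   ions (HexNAc⁺ 204.0867, NeuAc⁺ 292.1027, …) must be present, and the
   peptide backbone must be evidenced by the Y1 ion (peptide + GlcNAc)
   or by y/b fragment coverage.
4. **Quantifies** each accepted glycopeptide by summing the first seven
   isotopolog peaks from the MS1 scans of its retention-time window:
   targets m/z₀ + k·1.0033548/z (k = 0…6), one most-intense peak per
   scan within ±0.015 m/z, missing peaks counting zero.
5. **Profiles** each site: abundances of identical compositions are
   summed across peptides and charge states, normalized within the
   site, and classified as oligomannose / hybrid / complex / truncated
   by a declarative composition-rule table; reports include per-site
   type fractions, top-k glycoforms and distinct-glycopeptide summary
   tables.

A companion module computes qRT-PCR fold changes by the 2^−ΔΔCt method
(ΔCt against the arithmetic mean of the ACTB/B2M/GAPDH/RPLP0/HPRT1
housekeeping panel) and the R² concordance of log₂ fold changes between
qPCR and RNA-Seq, with leave-one-out influence analysis.

Because real acquisitions are large and vendor-locked, the package ships
a ground-truth simulator (`glycoquant.synthetic`) that generates runs
with known site profiles, isotopolog envelopes, m/z jitter, intensity
noise, decoy peaks and diagnostic-ion MS2 spectra, so the whole chain is
testable end to end.

## Worked example

```python
from glycoquant import synthetic
from glycoquant.pipeline import PipelineConfig, run_pipeline

gt = synthetic.default_scenario(seed=1)          # 5 sites, 50 glycoforms
run, truth = synthetic.simulate_run(gt)          # noisy LC-MS run
cfg = PipelineConfig(site_labels=synthetic.DEMO_SITE_LABELS)
bundle = run_pipeline(run, synthetic.DEMO_PROTEIN, cfg)

print(f"identified {len(bundle['identifications'])} glycopeptide spectra")
for site in sorted(bundle["profiles"]):
    cf = bundle["profiles"][site].class_fractions
    print(site, " ".join(f"{k}={v:.3f}" for k, v in cf.items() if v > 0))
```

prints

```
identified 50 glycopeptide spectra
N162 oligomannose=0.161 hybrid=0.418 complex=0.421
N169 oligomannose=0.080 hybrid=0.101 complex=0.640 truncated=0.179
N38 oligomannose=0.400 hybrid=0.100 complex=0.500
N45 oligomannose=0.160 hybrid=0.659 complex=0.181
N74 oligomannose=0.100 hybrid=0.060 complex=0.839
```

i.e. every planted glycopeptide was identified, and the recovered
glycan-type fractions per site (each row sums to 1) match the simulated
truth — N38 was planted at 40/10/50% oligomannose/hybrid/complex — to a
fraction of a percentage point despite 5% intensity noise, 0.003 m/z
jitter and decoy peaks. `bundle["summary_table"]` adds the
distinct-glycopeptide counts and mass-error statistics
(50 glycopeptides, 27 distinct compositions, mean |error| 0.0025 Da for
this run).

The same stages are available from a shell:

```bash
glycoquant simulate --out sim --seed 1
glycoquant run sim/synthetic.mgf sim/protein.fasta --out reports
glycoquant expression ct.tsv --groups s1=primary,s2=cell_line \
    --test cell_line --reference primary
```

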