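# Methods

## Scope and model

`glycoquant` is a *targeted* single-protein glycoproteomics pipeline. It
assumes the analyte is one purified glycoprotein whose sequence is
known, digested with proteases of known specificity, and acquired as
centroided MS1/MS2 spectra. Under those assumptions a database search
engine is unnecessary: the candidate space is the cross product of the
protein's single-sequon peptides with a bounded grid of N-glycan
compositions, and identification reduces to precursor mass matching
plus diagnostic-ion validation.

Glycans are represented as residue-count compositions
(HexNAc, Hex, dHex, NeuAc), never as structures. Everything downstream
— mass arithmetic, classification, reporting — is composition-level,
and isobaric structures are explicitly not distinguished.

## Mass and isotope arithmetic

All masses derive from one atomic table (`pyteomics.mass.nist_mass`,
IUPAC isotopic compositions). Residue masses are computed from
elemental formulas at run time: amino acids from
`pyteomics.mass.std_aa_comp`, glycosyl residues from C8H13NO5 (HexNAc),
C6H10O5 (Hex), C6H10O4 (dHex), C11H17NO8 (NeuAc), carbamidomethyl from
C2H3NO (+57.021464 Da, fixed on Cys to model iodoacetamide alkylation).

Isotopolog envelopes are *aggregated* (unit-mass-binned): isotopologs
are grouped by neutron-count offset and the inter-peak spacing is
approximated by the ¹³C−¹²C mass difference, 1.0033548 Da. This matches
how the extraction stage targets peaks — at a 0.015 m/z selection
window, fine isotopic structure is unresolvable — and makes simulated
and extracted envelopes directly comparable. The envelope of a formula
is computed by truncated polynomial convolution: each element's
per-atom offset distribution is raised to its atom count by binary
exponentiation with truncation to the requested number of peaks, the
element polynomials are convolved, and the retained peaks are
renormalized to sum to 1. Truncation-then-renormalization is applied
identically in the simulator and in the comparison of extracted
envelopes, so the two are commensurable. An independent oracle
(exhaustive stars-and-bars enumeration with exact multinomial weights)
is kept in the test suite and the acceptance script; the two routes
agree to < 1e-8 absolute abundance on random peptide+glycan formulas.

## Digestion

Two proteases are modeled as one combined specificity set: chymotrypsin
cleaving C-terminal to F/W/Y/L and Glu-C C-terminal to E (the
ammonium-bicarbonate convention; cleavage at D can be added via the
specificity string). Cleavage is suppressed before proline. The default
`max_missed = 2` reflects that glycan-occupied sequons suppress
cleavage in practice, so glycopeptides frequently retain missed sites.
Coordinates are 1-based inclusive. Digestion is verified against two
independent routes: brute-force enumeration over all subsets of
cleavage sites, and `pyteomics.parser.cleave` with the equivalent
regular expression.

Only peptides containing exactly one complete sequon enter the
glycopeptide library: with a single sequon, an identified glycoform is
attributable to one site without any localization machinery.
Multi-sequon peptides are rejected rather than ambiguously assigned.

## Identification and validation

A candidate matches an MS2 spectrum when
|z·(m/z_obs − m_proton) − M_theo| ≤ `precursor_tol_da` (default
0.015 Da — the same window used for MS1 peak selection; the two
tolerances are configurable independently). Validation then requires:

* at least one glycan oxonium ion (HexNAc⁺ 204.0867 and its water/
  CH₂O-loss fragments, HexHexNAc⁺ 366.1395, NeuAc⁺ 292.1027,
  NeuAc−H₂O⁺ 274.0921; all computed from elemental formulas) within
  `oxonium_tol_mz` (default 0.02);
* backbone evidence: the Y1 ion (peptide + one GlcNAc, charges 1–2 by
  default) **or** y/b fragment coverage ≥ `backbone_min_coverage`
  (default 0.25, a deliberately permissive floor since Y1 is the
  primary criterion for glycopeptide spectra, where backbone fragments
  are often sparse).

A peptide+partial-glycan Y-ion ladder count is reported as additional
evidence but does not gate acceptance. When several candidates match
one spectrum, accepted candidates beat rejected ones and the smallest
absolute precursor error wins. No FDR is estimated: the search space is
one protein, and decoy-based discrimination checks live in the test
suite, not the pipeline. The default composition grid is HexNAc 2–8,
Hex 3–12, dHex 0–4, NeuAc 0–4, pruned by the biosynthetic constraint
NeuAc ≤ max(0, HexNAc − 2) (a sialic acid needs an antenna GlcNAc to
cap).

## Quantification

For each accepted glycopeptide and charge state, the extractor visits
every MS1 scan in the retention-time window (identification RT ±
`rt_half_width`, default 0.5 min) and, for each of the first
`n_isotopologs = 7` targets m/z₀ + k·1.0033548/z, takes the single most
intense peak within ±`quant_tol_mz` (default 0.015 m/z). Taking the
most intense peak rather than the sum of all peaks in the window
resists chimeric neighbours; both the window rule and the per-scan rule
are configurable. Intensities are summed over scans and then over the
seven isotopologs; missing peaks contribute zero. Charge states are
quantified separately and summed during profiling.

## Profiling

Within one sample, abundances of identical compositions at the same
site are summed across peptides and charge states; fractions are
normalized within each (sample, site) pair and never across sites. A
site with zero accepted signal is reported as "n.d." (explicit missing
value), not as zeros. The maturity classification is a first-match rule
table over composition bounds:

1. truncated — HexNAc ≤ 2 and Hex < 5 (paucimannose/core fragments);
2. oligomannose — HexNAc = 2, Hex ≥ 5, no dHex/NeuAc;
3. hybrid — HexNAc = 3 with Hex ≥ 5, or HexNAc = 2 with Hex ≥ 5 and at
   least one decoration (dHex + NeuAc ≥ 1);
4. complex — everything else.

These are the standard composition heuristics of glycoproteomics search
tools. Because composition cannot resolve isobaric structures (e.g. a
bisecting GlcNAc), the table is a replaceable data structure: alternate
conventions — such as whether monofucosylated HexNAc-3 forms should
count as hybrid — can be audited by swapping rule rows rather than
editing code. An exhaustive enumeration test guarantees the table is a
total partition of composition space. Summary tables count distinct
(peptide, site, glycan) triples — charge states and repeat spectra of
one triple count once — and report the mean ± SD of absolute precursor
mass errors, with distinct-composition counts per sample and overall.

## Expression concordance

ΔCt is computed per sample against the arithmetic mean of the five-gene
housekeeping panel (ACTB, B2M, GAPDH, RPLP0, HPRT1), ΔΔCt as the
difference of group means (test − reference), and the fold change as
2^−ΔΔCt. Cross-method concordance (qPCR vs RNA-Seq) is the squared
Pearson correlation of fold changes, computed on log₂ scale by default:
on the linear scale a single large fold change dominates the
correlation, whereas on the log scale such a point is instead exposed
by the leave-one-out profile, which reports R² after dropping each gene
and flags the most influential one. A linear-scale mode is provided and
flagged in the output. RNA-Seq differential-expression fitting itself
is out of scope; the module consumes fold-change tables.

## The synthetic generator

`glycoquant.synthetic` emulates the statistical structure the pipeline
assumes, not a full instrument. `DEMO_PROTEIN` is a synthetic
200-residue construct (labelled synthetic; it is not a natural
sequence) with sequons at positions 38/45/74/162/169 arranged so each
site yields a fully cleaved single-sequon peptide. MS1 scans are
generated on a fixed RT grid (0.1 min spacing); each glycopeptide's
seven-peak envelope is scaled by a truncated-Gaussian elution profile
(SD 0.15 min, window ±0.4 min, one apex per glycopeptide spaced 1 min
apart) whose per-window weights are normalized so the planted total
equals the true intensity exactly — this is what makes the zero-noise
closed loop an equality test at 1e-9 rather than an approximation. The
default noise model is 5% multiplicative (lognormal) intensity noise,
0.003 Da m/z jitter (well inside the 0.015 selection window), and 20
uniform decoy peaks per scan; MS2 spectra carry the oxonium, Y1,
backbone and Y-ladder ions at theoretical m/z. Truth RT windows are
widened by half a scan interval so grid rounding cannot drop an edge
scan. Ct tables are generated by exact 2^−ΔΔCt inversion from true fold
changes plus N(0, σ²) cycle noise; with σ = 0.1 and n = 4 replicates
the recovered log₂ fold change has standard error
σ·√(2.4/n) ≈ 0.077 (four noisy group means and a five-gene
housekeeping mean enter the estimate).

The default five-site scenario (10 glycoforms per site, fixed weights)
exercises all four classifier branches: a mixed 40/10/50 site, a
hybrid-dominated site, a processed sialylated/fucosylated site, a
balanced site and a site with truncated forms. Sample sizes were chosen
so the whole loop — simulation, search against the ~17k-candidate
library, quantification, profiling — completes in seconds on one core.

What the simulator deliberately omits, and what passing tests therefore
do *not* demonstrate about real data: chromatographic co-elution and
chimeric envelopes, peak-shape variation and saturation, profile-mode
data, retention-time drift between runs, in-source fragmentation, and
the behaviour of commercial open/database search engines. The recovery guarantees hold
for well-separated analytes at the stated noise levels.

## Numerical and degenerate-input conventions

* Proton mass 1.00727646677 Da; all envelopes renormalized over the
  retained peaks; envelope/oracle agreement asserted at 1e-8.
* Spectra are sorted by m/z on construction; exact-duplicate centroids
  are merged by summing. Runs are sorted by RT.
* Empty inputs degrade with warnings, not crashes: empty files → empty
  runs; an empty RT window → all-zero intensities; a too-short peptide
  → backbone coverage 0; genes missing in the reference group are
  omitted from fold-change output.
* Ranking ties in top-k glycoforms break on the
  (HexNAc, Hex, dHex, NeuAc) tuple, so reports are deterministic.
* All simulator randomness flows from an explicit integer seed; there
  is no wall-clock entropy, and a fixed seed reproduces byte-identical
  output files.

## Known limitations

Single-protein scope (no proteome-wide search); composition-level only
(no linkage/topology, no isobaric resolution); no site localization for
multi-sequon peptides (they are excluded); no chromatographic peak
fitting or deconvolution; no label-based quantification; MGF/TSV
centroid interchange only (vendor RAW conversion is assumed upstream).
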