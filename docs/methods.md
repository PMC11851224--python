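# Methods

## Scope and model

`nglycofind` identifies N-linked glycopeptides from centroided,
stepped-HCD-style MS/MS peak lists. The underlying fragmentation model:

* N-glycans occupy Asn only within the sequon N-X-S/T (X ≠ P).
* Under collisional fragmentation the glycosidic bonds break before the
  peptide backbone is exhausted, producing **B ions** (glycan fragments
  carrying the charge, oxonium-type, m/z = residue masses − losses·H₂O
  + z·proton over z) and **Y ions** (intact peptide retaining part of
  the glycan; Y0/Y1/Y2 = peptide + 0/1/2 core HexNAc).
* The Asn–GlcNAc bond is comparatively stable, so peptide b/y fragments
  spanning the glycosite retain one core HexNAc (+203.0794 Da).
* Cation adducts (NH4⁺, Fe³⁺, Al³⁺, …) displace ionizing protons; the
  neutral-mass shift is the electron-corrected cation mass minus the
  displaced protons (NH4 +17.026549, Fe[III] +52.911462,
  Al[III] +23.958063 Da). Metal adducts ride along on glycan Y
  fragments; ammonium does not, so an NH4 spectrum looks like the
  protonated one apart from its precursor.

Glycans are treated as residue **compositions** only (e.g.
`HexNAc4Hex5NeuGc2`); topology and linkage are out of scope. Residue
tokens: HexNAc, Hex, Fuc, NeuAc, NeuGc, their O-acetylated sialic forms
NeuAcAc/NeuGcAc as distinct tokens (+C₂H₂O), and mass-only Phospho and
Sulfo markers. Monoisotopic masses come from pyteomics element tables;
residue masses are condensed-chain masses (free sugar − H₂O).

## Workflow stages and parameters

**Oxonium filter.** A spectrum passes if it contains the HexNAc oxonium
ion at m/z 204.0866 within `tol_ppm` (default 20) at or above
`min_relative_intensity` of the base peak (default 0, i.e. no floor —
whether an intensity floor helps is dataset-dependent and the
conservative default is none). Additional ions (e.g. 138.055) can be
required in any-of/all-of mode.

**Database search.** Fully tryptic digestion (cleave after K/R, not
before P), 0–3 missed cleavages, peptide length 5–60. Variable
modifications: Oxidation (M), Gln→pyro-Glu (N-terminal Q), and protein
N-terminal Met-removal/acetylation permutations, at most 2 variable
mods per peptide (tractability defaults, configurable). Precursor
tolerance 5 ppm, fragment tolerance 20 ppm. Only sequon-containing
peptides are glycopeptide candidates; the precursor must equal peptide
+ glycan for some glycan in the set (no adducts, no isotope offsets at
this stage). Glycan oxonium/B peaks from a catalogued diagnostic list
are stripped before peptide scoring.

*Peptide score.* The number of distinct b/y fragments (charges 1 to
precursor charge − 1; glycosite-spanning fragments +HexNAc) matched at
20 ppm, plus one point when the Y1 ion is present, with the matched
intensity sum used only to break ties. The scoring function of the
search engine this workflow is modelled on is unpublished, so this
transparent matched-ion count is the package's own choice, isolated
behind `score_peptide` and swappable.

*FDR.* Decoys are seeded uniform within-protein shuffles (length and
composition preserved, `DECOY_` accession prefix, one per target). The
unique-peptide threshold is the lowest score at which
#decoys ≥ t / #targets ≥ t stays at or below the target rate (default
1%), maximizing accepted targets; proteins are then thresholded the
same way with protein score = best peptide score. With zero decoy
matches the estimate is undefined and the operation raises unless the
caller opts into accept-all (`allow_no_decoys`), which the CLI does
with a warning.

**Y1 glycoform expansion.** Seeds are the unique (sequence, non-glycan
mods) of FDR-accepted target matches, with protein references, mean
retention time and spread aggregated. For every filtered spectrum and
seed, all (glycan, adduct, isotope offset) triples satisfying

|precursor − offset·1.003355 − (peptide + glycan + adduct)| ≤ 5 ppm

are enumerated exhaustively (offsets −1/0/+1 absorb wrong
monoisotopic-peak picks; the precursor tolerance is reused from the
search stage). A candidate survives only if the required Y series
(default {Y1}) is present at 20 ppm at some charge 1..z; for metal
adducts both the plain and adduct-shifted Y m/z are probed. Surviving
candidates are scored (below); the best must reach peptide score ≥ 0
and glyco score ≥ 5. Ranking: glyco score, peptide score, smaller
|offset|, no-adduct before adduct, composition string. A runner-up
within 1 glyco-score point sets an `ambiguous` flag naming it — near-
isobars are reported, not silently resolved. One assignment per (file,
scan) is kept after sorting by file, scan, glyco score, peptide score.

## Glycan scoring

Expected fragments for a candidate (peptide, glycan, adduct):

* **Y series** — the core ladder (HexNAc1, HexNAc2, optionally with
  core fucose, then HexNAc2Hex1..n) plus bounded antenna completions
  (HexNAc′ 2..n, Hex′ 3..n, Fuc′ and sialic counts up to the
  composition), capped at 400 fragments; phospho/sulfo are retained
  only on the full structure. Enumerating the full sub-composition
  lattice would explode combinatorially for large glycans and adds no
  discriminating power at this mass accuracy.
* **B series** — all sub-compositions of 1–4 residues (the cap covers
  every diagnostic ion of practical size, up to HexNAcHexNeuGcAc at
  m/z 715.240), sialic-containing ones also with one water loss, and
  Hex±Phospho ions for phosphoglycans.

Score = (+1 per matched expected fragment group) + penalties. Isobaric
expected fragments — e.g. the Hex+NeuAc vs Fuc+NeuGc sub-glycan pair,
identical to the microdalton — are grouped by (series, neutral mass
rounded to 1 mDa) so one observed peak earns one point. Penalties
(defaults; all configurable in `GlycoScoreConfig`):

* −5 per sialic type present in the candidate with no matching sialic
  B ion observed. Sialic oxonium ions observed but *not* in the
  candidate cost nothing: they are pervasive co-isolation background.
* −1 when the candidate contains fucose but no Fuc-containing B or Y
  ion matched.
* −1 per catalogued non-sialic diagnostic ion observed that implies
  residues absent from the candidate (e.g. Hex+Phospho under a
  phosphate-free candidate).

The magnitudes are this package's choices — the qualitative rules
(heavy sialic penalty, small fucose penalty) are the established
practice, the numbers are not published — and with the default +1
points the acceptance threshold of 5 means five net supporting ions.
Intensity is deliberately absent from the score; it is used only for
tie-breaks and for flagging rearrangement products: a peptide+HexNAcHex
Y peak (impossible from an intact N-glycan topology) exceeding 5% of
the Y1 intensity marks the match `rearrangement`.

`background_ion_stats` tabulates, over final matches, how often each
catalogued B ion and the Y+HexNAcHex indicator is observed and observed-
but-not-expected — the empirical basis for the sialic asymmetry above.

## Reporting and decoy-adduct FDR

Spectral matches collapse to unique glycopeptides on (peptide sequence,
non-glycan mods, glycan) with the adduct stripped, and further to
glycosylated sequences, with a glycoforms-per-sequence histogram.
Aluminum (assumed absent from real samples, `plausible=False`) serves
as the decoy adduct: with *d* aluminum spectral matches, each accepted
class (no-adduct plus each plausible searched adduct) is assumed to
contain a similar number of random matches, giving per-class FDR
d/n_class and overall FDR k·d/N for k classes and N total matches. Per-
class counts are deliberately *not* scaled by class search-space size
(the unscaled similar-number assumption is what the estimator states).
Decoy-adduct matches are removed from all downstream reports. Adducted
matches whose (peptide, glycan) never occurs unadducted are flagged
`no-protonated-support`: adducts are low-intensity satellites of the
protonated form, so an orphan adduct assignment is almost certainly
wrong.

## Synthetic data generator

`nglycofind.simulate` emulates a merged stepped-HCD peak list per
spectrum: peptide b/y ions (glycosite +HexNAc), the glycan Y core
ladder plus the full composition, plausible B ions, each retained with
`fragment_efficiency` (default 0.9); log-normal intensities; ppm-scale
mass jitter (default 1.5 ppm, inside the 5 ppm precursor tolerance);
uniform noise peaks (default 20). Background co-isolation is modelled
as a bundle of HexNAc and NeuAc/NeuGc oxonium ions injected into any
spectrum with probability `oxonium_contamination` (default 0.98 — in
enriched samples essentially every spectrum shows m/z 204) at 1–5% of
the base peak. Rearrangement peaks (peptide+HexNAcHex) appear in 23% of
glycopeptide spectra at under 5% of the Y1 intensity. Metal-adducted
spectra shift glycan-bearing Y ions by the adduct mass; ammonium
spectra do not. Default populations: an oligomannose-rich glycan
frequency table with sialylated biantennary, fucosylated and
phosphorylated species; NH4 on 21% and Fe on 7% of glycopeptide
spectra; charges 2/3/4 at 45/40/15%. The first observation of each
glycopeptide sequence is always fully protonated at the correct
monoisotopic peak — adducts occur as satellites of an observed
protonated form, which also makes every sequence seedable by the
search stage. A `junk_fraction` adds chimera-like spectra matching a
random (glycan, adduct class) uniformly over the accepted classes plus
the decoy-adduct class: the random-match population the decoy-adduct
estimator is built to count, used by the calibration study.

Not modelled: isotope envelopes (monoisotopic sticks only; ±1-isotope
errors are injected explicitly via precursor offsets), chromatographic
elution beyond a per-peptide retention time, per-step sub-spectra of
the stepped acquisition, and realistic intensity structure. Passing
tests on this generator therefore demonstrate the mass algebra,
enumeration, scoring logic and estimator calibration — not performance
on instrument data, where peak-picking artifacts, chimeric precursors
and intensity effects are harsher.

## Numerical choices and problem sizes

Proton 1.00727647 Da, electron 0.00054858 Da, water 18.010565 Da,
isotope spacing 1.003355 Da; element masses from pyteomics. Peak
matching is binary search over the sorted m/z array with windows of
target·ppm·10⁻⁶. Ties in FDR thresholding group equal scores before
evaluating the decoy/target ratio. The default mammalian N-glycan set
is generated (≈1000 compositions: oligomannose HexNAc2Hex4–12 with
mannose-6-phosphate variants, truncated/paucimannose cores, and
complex/hybrid permutations constrained by antenna count — sialic
residues ≤ HexNAc−2, Hex ≤ 3+2·antennae, bounded fucosylation and
O-acetylation); user lists override it, since the glycan search space
is itself a first-order determinant of identification results. The
test suite's simulation studies use 200 glycopeptide spectra for the
noiseless closure, 2000 spectra for the decoy-adduct calibration, 40
spectra for the ammonium stress test and 1000 random precursors for
the enumeration oracle — sizes at which the binomial tolerances in the
assertions are meaningful while the whole suite stays fast.

## Known limitations

* Composition-level assignment only; topologically impossible
  compositions are not excluded beyond the antenna constraints.
* The peptide score is a matched-ion count; spectra with few backbone
  fragments rely almost entirely on the Y1 requirement and glyco score.
* O-glycopeptides, ETD/EThcD fragmentation and spectral-library search
  are out of scope.
* The decoy-adduct estimator inherits the similar-number assumption;
  if the decoy adduct's random-match propensity differs from the
  accepted classes, the estimate biases accordingly.
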