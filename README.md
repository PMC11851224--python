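# nglycofind

Identification of N-glycopeptides from stepped-HCD tandem mass spectra,
built around a three-stage, peptide-first workflow:

1. **Oxonium filtering** — keep MS/MS spectra showing the HexNAc oxonium
   ion at m/z 204.087 (20 ppm), the signature of a glycopeptide
   precursor.
2. **Peptide-first database search** — fully tryptic digestion with
   sequence-randomized decoys; for each spectrum, sequon-containing
   peptides (N-X-S/T, X ≠ P) whose neutral mass plus a glycan-set mass
   explains the precursor within 5 ppm are scored on b/y ions, with the
   core HexNAc retained on glycosite-spanning fragments and glycan
   oxonium peaks stripped first. Results are thresholded by target-decoy
   FDR at the unique-peptide and protein level. The glycan is assigned
   by mass alone at this stage.
3. **Y1-driven glycoform expansion** — each confidently identified
   peptide sequence becomes a *seed*; every filtered spectrum showing
   the seed's Y1 ion (peptide + HexNAc) is tested against all
   (glycan, adduct, isotope offset) combinations explaining its
   precursor, and each candidate is scored on glycan B and Y ions.
   This recovers the many glycoforms of a peptide that never earn a
   confident identification on their own.

The package is aimed at glycoproteomics method developers: everything is
importable (`nglycofind` the library), scriptable (`examples/`), and a
thin CLI (`nglycofind simulate|filter|search|expand|report`) chains the
stages over MGF/FASTA/TSV files. A deterministic synthetic-spectrum
generator (`nglycofind.simulate`) stands in for instrument data, so the
whole pipeline is testable offline.

## Why adducts matter

Glycopeptides pick up ammonium and metal cation adducts far more than
plain peptides, and the mass algebra is treacherous:

* `HexNAc2Hex9 + NH4` is **0.994 Da** (≈ one isotope spacing) above
  `HexNAc4Hex3NeuAc2` on the same peptide — a search allowing ±1
  monoisotopic-peak errors but no adducts will systematically report the
  sialylated glycan;
* `NeuGc + NH4` is only **0.011 Da** away from two hexoses — within a
  5 ppm window above ~2.2 kDa.

`nglycofind` searches ammonium and iron adducts (iron additionally
shifting glycan Y ions, ammonium only the precursor), and deliberately
also searches an adduct believed absent from real samples — aluminum —
as a **decoy adduct**. With *d* decoy-adduct spectral matches and *k*
accepted assignment classes (no adduct, NH4, Fe) totalling *N* spectral
matches, the estimated per-class error is *d/n_class* and the overall
error *k·d/N*: the same "random matches hit every class equally" logic
as target-decoy FDR, applied to glycan assignment.

Glycan candidates are scored by counting supporting minus contradicting
B/Y ions, with two field-motivated asymmetries: sialic-acid oxonium ions
are such common co-isolation background that their *presence* never
counts against a sialic-free candidate, while their *absence* under a
sialylated candidate is penalized −5; a fucosylated candidate with no
fucose-containing fragment matched takes a −1 penalty (this separates
+Hex from +Fuc+NH4). Exact ties and near-ties are reported with an
`ambiguous` flag naming the runner-up rather than silently resolved.

## Worked example

`python examples/05_ammonium_isobar.py` simulates twenty NH4-adducted
`HexNAc2Hex9` glycopeptide spectra and assigns them with and without
ammonium in the adduct list:

```
20 NH4-adducted HexNAc2Hex9 spectra, truth = HexNAc2Hex9+NH4@+0

  without NH4:
     20 x HexNAc4Hex3NeuAc2+none@+1
  with NH4:
     20 x HexNAc2Hex9+NH4@+0
```

Without the adduct, every spectrum drifts to the sialylated isobar one
isotope up — the characteristic failure of peptide-first engines — and
with it, every spectrum is correct. `examples/04_glycoform_expansion.py`
runs the full pipeline on a noisy 143-spectrum dataset and prints the
expansion gain and the decoy-adduct FDR:

```
39 seed peptides from the database search
100 spectral assignments after Y1 expansion (vs 90 from the search alone)
decoy-adduct FDR: overall 0.0%  per class: Fe[III] 0.0%, NH4 0.0%, none 0.0%
unique glycopeptides (adduct stripped): 93; sequences: 37; mean glycoforms/sequence: 2.5
```

The other examples cover the mass arithmetic (`01`), simulation and
filtering (`02`), and the database search (`03`).

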