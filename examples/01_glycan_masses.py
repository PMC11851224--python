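"""Glycan mass arithmetic: compositions, oxonium ions and adduct isobars.

Computes the diagnostic ion masses a glycoproteomics analyst keeps in
their head, and the two near-isobars that make ammonium adducts so
treacherous for glycan assignment.
"""

from nglycofind import (
    GlycanComposition,
    adduct_mass_shift,
    composition_mass,
    get_adduct,
    glycopeptide_neutral_mass,
    oxonium_mz,
    parse_composition,
)

G = parse_composition

print("residue masses (Da):")
for name in ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc"):
    print(f"  {name:8s} {composition_mass(G(name)):10.4f}")

print("\ndiagnostic oxonium ions (1+, m/z):")
for label, comp, losses in [
    ("HexNAc", "HexNAc", 0),
    ("NeuGc -H2O", "NeuGc", 1),
    ("NeuGc", "NeuGc", 0),
    ("NeuGcAc -H2O", "NeuGcAc", 1),
    ("NeuGcAc", "NeuGcAc", 0),
    ("HexNAcHexNeuGcAc", "HexNAcHexNeuGcAc", 0),
    ("Hex+Phospho", "HexPhospho", 0),
]:
    print(f"  {label:18s} {oxonium_mz(G(comp), losses):9.3f}")

# Why ammonium adducts corrupt glycan assignment: on the same peptide,
# HexNAc2Hex9 + NH4 sits 0.994 Da (~one isotope) above HexNAc4Hex3NeuAc2,
# and NeuGc + NH4 is only 0.011 Da away from two plain hexoses.
pep = 1200.0
gap1 = glycopeptide_neutral_mass(pep, G("HexNAc2Hex9"), get_adduct("NH4")) - (
    glycopeptide_neutral_mass(pep, G("HexNAc4Hex3NeuAc2"))
)
gap2 = composition_mass(G("NeuGc")) + adduct_mass_shift("NH4") - composition_mass(G("Hex2"))
print(f"\nHexNAc2Hex9+NH4 vs HexNAc4Hex3NeuAc2 : {gap1:+.3f} Da (one isotope spacing)")
print(f"NeuGc+NH4       vs 2 x Hex            : {gap2:+.3f} Da (inside 5 ppm above ~2.2 kDa)")
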