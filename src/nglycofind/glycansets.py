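"""Built-in N-glycan composition sets and glycan-list file I/O.

The default mammalian set is a generated approximation of the kind of
composition list a search engine ships for CID data on mammalian samples:
oligomannose (with optional mannose-6-phosphate), paucimannose/truncated
structures, and hybrid/complex permutations of HexNAc/Hex/Fuc with NeuAc,
NeuGc and their O-acetylated variants, under antenna-consistency
constraints (sialic residues never exceed the antenna count HexNAc−2).
Users replace it with their own plain-text list when they have matched
glycomics data.
"""

from __future__ import annotations

from itertools import product
from pathlib import Path
from typing import Iterable

from .chem import GlycanComposition, RESIDUE_ORDER


def _sialic_combos(max_total: int, allow_acetyl: bool):
    """(NeuAc, NeuAcAc, NeuGc, NeuGcAc) tuples with total <= max_total."""
    ac_max = 1 if allow_acetyl else 0
    for neuac, neugc, aa, ga in product(
        range(min(max_total, 4) + 1),
        range(min(max_total, 4) + 1),
        range(ac_max + 1),
        range(ac_max + 1),
    ):
        if neuac + neugc + aa + ga <= max_total:
            yield neuac, aa, neugc, ga


def default_glycan_set(kind: str = "mammalian-N") -> list[GlycanComposition]:
    """Generate the default mammalian N-glycan composition set.

    Deterministic order (sorted by residue-count vector); deduplicated;
    roughly a thousand entries.
    """
    if kind != "mammalian-N":
        raise ValueError(f"unknown glycan set kind {kind!r}")
    out: set[GlycanComposition] = set()

    def add(**counts: int) -> None:
        out.add(GlycanComposition.from_dict({k: v for k, v in counts.items() if v}))

    # oligomannose HexNAc2Hex4-12, mannose-6-phosphate variants on Hex>=5
    for hexn in range(4, 13):
        add(HexNAc=2, Hex=hexn)
        if hexn >= 5:
            add(HexNAc=2, Hex=hexn, Phospho=1)

    # paucimannose / truncated cores, optional core fucose
    for hexnac in (1, 2):
        for hexn in range(0, 4):
            for fuc in (0, 1):
                add(HexNAc=hexnac, Hex=hexn, Fuc=fuc)

    # hybrid/complex: antennae a = HexNAc - 2
    for a in range(1, 6):
        hexnac = a + 2
        hex_max = min(10, 3 + 2 * a)
        fuc_max = min(2, a) if a < 4 else 1
        allow_acetyl = a <= 2
        for hexn in range(3, hex_max + 1):
            for fuc in range(0, fuc_max + 1):
                for neuac, aa, neugc, ga in _sialic_combos(a, allow_acetyl):
                    add(
                        HexNAc=hexnac,
                        Hex=hexn,
                        Fuc=fuc,
                        NeuAc=neuac,
                        NeuAcAc=aa,
                        NeuGc=neugc,
                        NeuGcAc=ga,
                    )

    def key(c: GlycanComposition):
        d = c.as_dict()
        return tuple(d.get(t, 0) for t in RESIDUE_ORDER)

    return sorted(out, key=key)


def write_glycan_list(glycans: Iterable[GlycanComposition], path) -> None:
    """Write one canonical composition string per line ('#' comments allowed)."""
    with open(path, "w") as fh:
        for g in glycans:
            fh.write(str(g) + "\n")


def read_glycan_list(path) -> list[GlycanComposition]:
    """Read a plain-text glycan list: one composition per line, '#' comments."""
    glycans = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            glycans.append(GlycanComposition.parse(line))
    return glycans
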