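"""Glycan and glycopeptide mass arithmetic.

Monosaccharide residue masses, glycan compositions and their canonical
string dialect (``HexNAc4Hex5NeuGc2``), oxonium/B/Y fragment m/z, cation
adduct algebra, and N-glycosylation sequon detection.

All masses are monoisotopic and in Daltons. A *residue* mass is the mass a
monosaccharide adds when condensed into a chain (free sugar minus water).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

PROTON = 1.00727646688
ELECTRON = 0.00054857990946
WATER = _pmass.calculate_mass(formula="H2O")
#: mass difference between adjacent isotope peaks (averagine C13-C12 spacing)
ISOTOPE_SPACING = 1.003355

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MonosaccharideDef:
    """A monosaccharide (or mass-only glycan modification) residue."""

    name: str
    elemental_formula: str
    residue_mass: float


def _residue(name: str, formula: str) -> MonosaccharideDef:
    return MonosaccharideDef(name, formula, _pmass.calculate_mass(formula=formula))


#: canonical residue order used by the composition string dialect
RESIDUE_ORDER = (
    "HexNAc",
    "Hex",
    "Fuc",
    "NeuAc",
    "NeuAcAc",
    "NeuGc",
    "NeuGcAc",
    "Phospho",
    "Sulfo",
)

MONOSACCHARIDES: dict[str, MonosaccharideDef] = {
    m.name: m
    for m in (
        _residue("HexNAc", "C8H13NO5"),
        _residue("Hex", "C6H10O5"),
        _residue("Fuc", "C6H10O4"),
        _residue("NeuAc", "C11H17NO8"),
        _residue("NeuAcAc", "C13H19NO9"),   # O-acetyl-NeuAc, distinct token
        _residue("NeuGc", "C11H17NO9"),
        _residue("NeuGcAc", "C13H19NO10"),  # O-acetyl-NeuGc, distinct token
        _residue("Phospho", "HPO3"),
        _residue("Sulfo", "SO3"),
    )
}

#: sialic-acid residue tokens (exempt from contradiction penalties in scoring)
SIALIC_TOKENS = frozenset({"NeuAc", "NeuAcAc", "NeuGc", "NeuGcAc"})

# longest-token-first so NeuAcAc is not split as NeuAc + garbage
_TOKEN_RE = re.compile(
    "(" + "|".join(sorted(RESIDUE_ORDER, key=len, reverse=True)) + r")(\d*)"
)


class CompositionError(ValueError):
    """Raised for malformed glycan composition strings."""


@dataclass(frozen=True)
class GlycanComposition:
    """A multiset of monosaccharide residue counts.

    Immutable and hashable; equality is by counts. The canonical string
    lists residues in :data:`RESIDUE_ORDER` and omits the count when 1,
    e.g. ``HexNAc4Hex5NeuAcNeuGc``.
    """

    counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        seen = {}
        for token, n in self.counts:
            if token not in MONOSACCHARIDES:
                raise CompositionError(f"unknown residue token {token!r}")
            if n < 0:
                raise CompositionError(f"negative count for {token!r}")
            if token in seen:
                raise CompositionError(f"duplicate token {token!r}")
            seen[token] = n
        # normalize: canonical order, zero counts dropped
        norm = tuple(
            (t, seen[t]) for t in RESIDUE_ORDER if seen.get(t, 0) > 0
        )
        object.__setattr__(self, "counts", norm)

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "GlycanComposition":
        return cls(tuple(counts.items()))

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        return parse_composition(text)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, token: str) -> int:
        return dict(self.counts).get(token, 0)

    def __len__(self) -> int:
        return sum(n for _, n in self.counts)

    def __bool__(self) -> bool:
        return len(self) > 0

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        d = self.as_dict()
        for t, n in other.counts:
            d[t] = d.get(t, 0) + n
        return GlycanComposition.from_dict(d)

    def __sub__(self, other: "GlycanComposition") -> "GlycanComposition":
        d = self.as_dict()
        for t, n in other.counts:
            d[t] = d.get(t, 0) - n
        return GlycanComposition.from_dict(d)  # raises if negative

    def contains(self, other: "GlycanComposition") -> bool:
        d = self.as_dict()
        return all(d.get(t, 0) >= n for t, n in other.counts)

    @property
    def mass(self) -> float:
        return composition_mass(self)

    def __str__(self) -> str:
        return format_composition(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanComposition({str(self)!r})"


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"HexNAc2Hex9"``.

    Residue tokens may appear in any order; an omitted count means 1. An
    explicit count must be a positive integer. Unknown tokens are an error
    that names the offending text.
    """
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise CompositionError(
                f"unrecognized residue token at {text[pos:pos + 12]!r} in {text!r}"
            )
        token, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n <= 0:
            raise CompositionError(f"count for {token!r} must be positive, got {n}")
        counts[token] = counts.get(token, 0) + n
        pos = m.end()
    return GlycanComposition.from_dict(counts)


def format_composition(c: GlycanComposition) -> str:
    """Canonical string form; count 1 is omitted (``NeuAcNeuGc`` style)."""
    parts = []
    for token, n in c.counts:
        parts.append(token if n == 1 else f"{token}{n}")
    return "".join(parts)


def composition_mass(c: GlycanComposition) -> float:
    """Additive monoisotopic residue-mass sum of a composition."""
    return sum(MONOSACCHARIDES[t].residue_mass * n for t, n in c.counts)


# ---------------------------------------------------------------------------
# adducts


@dataclass(frozen=True)
class Adduct:
    """A cation adduct that displaces one or more ionizing protons.

    ``neutral_mass_shift`` is the mass added to the *neutral* glycopeptide:
    cation monoisotopic mass (electron-corrected) minus the displaced
    protons. ``plausible=False`` marks a decoy adduct searched only to
    estimate false-assignment rates. ``retained_on_y_ions`` states whether
    glycan Y fragments carry the adduct (true for metals, not ammonium).
    """

    name: str
    cation_formula: str
    protons_displaced: int
    plausible: bool = True
    retained_on_y_ions: bool = False

    @property
    def cation_mass(self) -> float:
        if not self.cation_formula:
            return 0.0
        return (
            _pmass.calculate_mass(formula=self.cation_formula)
            - self.protons_displaced * ELECTRON
        )

    @property
    def neutral_mass_shift(self) -> float:
        return self.cation_mass - self.protons_displaced * PROTON


NO_ADDUCT = Adduct("none", "", 0, plausible=True, retained_on_y_ions=False)

#: default adduct table. Aluminum is the decoy adduct (believed absent from
#: real samples); metals ride along on glycan Y ions, ammonium does not.
ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        NO_ADDUCT,
        Adduct("NH4", "NH4", 1, plausible=True, retained_on_y_ions=False),
        Adduct("Fe[III]", "Fe", 3, plausible=True, retained_on_y_ions=True),
        Adduct("Al[III]", "Al", 3, plausible=False, retained_on_y_ions=True),
        Adduct("Ca[II]", "Ca", 2, plausible=True, retained_on_y_ions=True),
        Adduct("Na", "Na", 1, plausible=True, retained_on_y_ions=True),
    )
}


def adduct_mass_shift(a: Adduct | str) -> float:
    """Neutral mass shift of an adduct (by object or configured name)."""
    if isinstance(a, str):
        try:
            a = ADDUCTS[a]
        except KeyError:
            raise KeyError(f"unknown adduct name {a!r}") from None
    return a.neutral_mass_shift


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(f"unknown adduct name {name!r}") from None


# ---------------------------------------------------------------------------
# fragments


@dataclass(frozen=True)
class GlycanFragment:
    """A glycosidic B or Y fragment ion.

    B ions are glycan-only oxonium-type cations; Y ions retain the peptide
    plus ``sub_composition`` of the glycan. ``water_losses`` applies to B
    ions (sialic oxonium ions are commonly seen with one water lost).
    """

    sub_composition: GlycanComposition
    series: str  # "B" or "Y"
    water_losses: int = 0
    charge: int = 1
    mz: float = 0.0
    label: str = ""


def oxonium_mz(
    c: GlycanComposition, water_losses: int = 0, charge: int = 1
) -> float:
    """m/z of the oxonium/B ion of a (sub)composition.

    ``(residue mass sum − water_losses × H2O + charge × proton) / charge``.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if not c:
        raise ValueError("oxonium ion of an empty composition")
    m = composition_mass(c) - water_losses * WATER
    if m <= 0:
        raise ValueError("water losses exceed fragment mass")
    return (m + charge * PROTON) / charge


def y_ion_mz(
    peptide_mass: float,
    sub: GlycanComposition,
    charge: int = 1,
    adduct_shift: float = 0.0,
) -> float:
    """m/z of a Y ion: intact peptide (neutral, with water) + retained glycan."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = peptide_mass + composition_mass(sub) + adduct_shift
    return (neutral + charge * PROTON) / charge


def glycopeptide_neutral_mass(
    peptide_mass: float, c: GlycanComposition, a: Adduct = NO_ADDUCT
) -> float:
    """Neutral mass of peptide + glycan + adduct (exactly additive)."""
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    return peptide_mass + composition_mass(c) + a.neutral_mass_shift


def mz_from_neutral(neutral: float, charge: int) -> float:
    return (neutral + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON


# ---------------------------------------------------------------------------
# diagnostic oxonium catalogue

_C = GlycanComposition.parse


@dataclass(frozen=True)
class DiagnosticIon:
    """A catalogued low-mass glycan fragment ion (1+)."""

    label: str
    mz: float
    residues: GlycanComposition  # residue content the ion implies


def _diag(label: str, comp: str, losses: int = 0) -> DiagnosticIon:
    c = _C(comp)
    return DiagnosticIon(label, oxonium_mz(c, water_losses=losses), c)


#: HexNAc secondary fragments: cross-ring/dehydration products of the
#: HexNAc oxonium ion; all imply HexNAc only.
HEXNAC_204 = oxonium_mz(_C("HexNAc"))
HEXNAC_138 = _pmass.calculate_mass(formula="C7H7NO2") + PROTON
HEXNAC_126 = _pmass.calculate_mass(formula="C6H7NO2") + PROTON
HEXNAC_144 = _pmass.calculate_mass(formula="C6H9NO3") + PROTON

_HEXNAC_SECONDARY = tuple(
    DiagnosticIon(lbl, mzv, _C("HexNAc"))
    for lbl, mzv in (
        ("HexNAc-C2H6O3", HEXNAC_126),
        ("HexNAc-CH6O3", HEXNAC_138),
        ("HexNAc-CH4O2-H2O", HEXNAC_144),
        ("HexNAc-2H2O", oxonium_mz(_C("HexNAc"), 2)),
        ("HexNAc-H2O", oxonium_mz(_C("HexNAc"), 1)),
    )
)

#: catalogued diagnostic B/oxonium ions used for spectrum stripping,
#: contradiction checks and background statistics.
DIAGNOSTIC_IONS: tuple[DiagnosticIon, ...] = _HEXNAC_SECONDARY + tuple(
    _diag(lbl, comp, losses)
    for lbl, comp, losses in (
        ("Fuc-H2O", "Fuc", 1),
        ("Hex-H2O", "Hex", 1),
        ("Fuc", "Fuc", 0),
        ("Hex", "Hex", 0),
        ("HexNAc", "HexNAc", 0),
        ("Hex+Phospho", "HexPhospho", 0),
        ("NeuAc-H2O", "NeuAc", 1),
        ("NeuAc", "NeuAc", 0),
        ("NeuGc-H2O", "NeuGc", 1),
        ("NeuGc", "NeuGc", 0),
        ("NeuAcAc-H2O", "NeuAcAc", 1),
        ("Hex2", "Hex2", 0),
        ("NeuAcAc", "NeuAcAc", 0),
        ("NeuGcAc-H2O", "NeuGcAc", 1),
        ("NeuGcAc", "NeuGcAc", 0),
        ("HexNAcHex", "HexNAcHex", 0),
        ("HexNAc2", "HexNAc2", 0),
        ("Hex2+Phospho", "Hex2Phospho", 0),
        ("HexNAcFuc", "HexNAcFuc", 0),
        ("HexNAcHex2", "HexNAcHex2", 0),
        ("HexNAcHexFuc", "HexNAcHexFuc", 0),
        ("HexNAcHexNeuAc", "HexNAcHexNeuAc", 0),
        ("HexNAcHexNeuGc", "HexNAcHexNeuGc", 0),
        ("HexNAcHexNeuAcAc", "HexNAcHexNeuAcAc", 0),
        ("HexNAcHexNeuGcAc", "HexNAcHexNeuGcAc", 0),
        ("HexNAc2Hex", "HexNAc2Hex", 0),
    )
)


@lru_cache(maxsize=8)
def oxonium_strip_mz(max_mz: float = 800.0) -> tuple[float, ...]:
    """Sorted 1+ m/z values of every catalogued diagnostic glycan ion.

    Used by the search engine to remove glycan oxonium/B peaks before
    peptide scoring.
    """
    return tuple(sorted(i.mz for i in DIAGNOSTIC_IONS if i.mz <= max_mz))


# ---------------------------------------------------------------------------
# sequon detection

_SEQ_RE = re.compile(r"N(?=[^P][ST])")


def find_nglyco_motifs(sequence: str) -> list[int]:
    """0-based positions of Asn in the N-glycosylation sequon N-X-S/T, X≠P.

    Asn within two residues of the C terminus (no room for the sequon) is
    excluded. Non-standard characters raise ``ValueError``.
    """
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    return [m.start() for m in _SEQ_RE.finditer(sequence)]


def peptide_mass(sequence: str, mod_deltas: Iterable[float] = ()) -> float:
    """Neutral monoisotopic mass of a peptide with optional mod deltas."""
    return _pmass.fast_mass(sequence) + sum(mod_deltas)
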