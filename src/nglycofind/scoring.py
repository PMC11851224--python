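"""Glycan assignment scoring from B and Y fragment ions.

A candidate glycan earns points for every expected B (oxonium-type) or Y
(peptide + partial glycan) ion matched in the spectrum, and is penalized
for catalogued diagnostic ions that contradict it. Two asymmetries mirror
how stepped-HCD data behaves in practice:

* sialic-acid oxonium ions are ubiquitous background (co-isolation ghost
  peaks), so observing them never counts *against* a sialic-free
  candidate — but a sialylated candidate whose sialic oxonium ions are
  absent is heavily penalized;
* a fucosylated candidate with no fucose-containing B or Y ion matched
  takes a small penalty (this is what separates +Hex from +Fuc+ammonium).

Intensity is never part of the score; it is used only for rearrangement
flagging (peptide+HexNAcHex peaks, which cannot arise from an intact
N-glycan topology, are flagged when they exceed 5% of the Y1 intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    DIAGNOSTIC_IONS,
    SIALIC_TOKENS,
    Adduct,
    GlycanComposition,
    GlycanFragment,
    NO_ADDUCT,
    oxonium_mz,
    y_ion_mz,
)
from .msio import Spectrum, match_peaks


@dataclass(frozen=True)
class GlycoScoreConfig:
    point_per_supporting_ion: float = 1.0
    point_per_contradicting_ion: float = -1.0
    sialic_missing_penalty: float = -5.0
    fucose_unsupported_penalty: float = -1.0
    frag_tol_ppm: float = 20.0
    min_fragment_relative_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.point_per_supporting_ion < 0:
            raise ValueError("supporting-ion points must be >= 0")
        if (
            self.point_per_contradicting_ion > 0
            or self.sialic_missing_penalty > 0
            or self.fucose_unsupported_penalty > 0
        ):
            raise ValueError("penalties must be <= 0")


@dataclass
class FragmentLedger:
    """Per-candidate record of expected, matched and contradicting ions."""

    expected_b: list[GlycanFragment] = field(default_factory=list)
    expected_y: list[GlycanFragment] = field(default_factory=list)
    matched: list[tuple[GlycanFragment, float, float]] = field(default_factory=list)
    contradicting: list[tuple[str, float, float]] = field(default_factory=list)
    penalties: dict[str, float] = field(default_factory=dict)


MAX_B_SIZE = 4  # residues per B-ion sub-composition (covers all diagnostics)
_MAX_Y_FRAGMENTS = 400


@lru_cache(maxsize=512)
def _y_subcompositions(glycan: GlycanComposition) -> tuple[GlycanComposition, ...]:
    """Glycan sub-compositions retained on Y ions, smallest first.

    Core ladder (HexNAc1-2, optional core Fuc, then the Hex ladder on the
    chitobiose core) plus bounded antenna completions for hybrid/complex
    compositions (HexNAc' 2..n with Hex' >= 3). The empty composition (Y0)
    is always first.
    """
    g = glycan.as_dict()
    n_hexnac = g.get("HexNAc", 0)
    n_hex = g.get("Hex", 0)
    n_fuc = g.get("Fuc", 0)
    subs: set[GlycanComposition] = {GlycanComposition()}

    def add(**counts: int) -> None:
        c = {k: v for k, v in counts.items() if v}
        subs.add(GlycanComposition.from_dict(c))

    for k in (1, 2):
        if n_hexnac >= k:
            add(HexNAc=k)
            if n_fuc:  # core fucose riding on the ladder
                add(HexNAc=k, Fuc=1)
    if n_hexnac >= 2:
        for h in range(1, n_hex + 1):
            add(HexNAc=2, Hex=h)
            if n_fuc:
                add(HexNAc=2, Hex=h, Fuc=1)
        # antenna completions
        if n_hexnac > 2 and n_hex >= 3:
            sial_tokens = [t for t in SIALIC_TOKENS if g.get(t, 0)]
            sial_ranges = [range(g[t] + 1) for t in sial_tokens]
            for hn, h, f in product(
                range(2, n_hexnac + 1), range(3, n_hex + 1), range(n_fuc + 1)
            ):
                for sial in product(*sial_ranges) if sial_tokens else [()]:
                    add(HexNAc=hn, Hex=h, Fuc=f,
                        **dict(zip(sial_tokens, sial)))
    for extra in ("Phospho", "Sulfo"):
        if g.get(extra, 0):
            # phospho/sulfo retained on the full structure only
            add(**{**{k: v for k, v in g.items() if k != extra}, extra: g[extra]})
    subs.add(glycan)

    ordered = sorted(subs, key=lambda c: (c.mass, str(c)))
    if len(ordered) > _MAX_Y_FRAGMENTS:
        ordered = ordered[:_MAX_Y_FRAGMENTS - 1] + [glycan]
    return tuple(ordered)


@lru_cache(maxsize=512)
def _b_subcompositions(
    glycan: GlycanComposition,
) -> tuple[tuple[GlycanComposition, int], ...]:
    """(sub-composition, water_losses) pairs for expected B ions.

    All sub-compositions of 1..4 residues present in the composition;
    sialic-containing ones additionally with one water loss (the dominant
    form for free sialic oxonium ions).
    """
    tokens = [t for t, n in glycan.counts if t not in ("Phospho", "Sulfo")]
    counts = glycan.as_dict()
    subs: set[GlycanComposition] = set()
    ranges = [range(min(counts[t], MAX_B_SIZE) + 1) for t in tokens]
    for combo in product(*ranges):
        size = sum(combo)
        if 1 <= size <= MAX_B_SIZE:
            subs.add(
                GlycanComposition.from_dict(
                    {t: n for t, n in zip(tokens, combo) if n}
                )
            )
    # phospho rides on Hex-containing small B ions (mannose-6-phosphate)
    if counts.get("Phospho", 0):
        for h in (1, 2):
            if counts.get("Hex", 0) >= h:
                subs.add(GlycanComposition.from_dict({"Hex": h, "Phospho": 1}))
    out: list[tuple[GlycanComposition, int]] = []
    for c in sorted(subs, key=lambda c: (c.mass, str(c))):
        out.append((c, 0))
        if any(c[t] for t in SIALIC_TOKENS):
            out.append((c, 1))
    return tuple(out)


def expected_fragments(
    peptide_mass: float,
    glycan: GlycanComposition,
    adduct: Adduct = NO_ADDUCT,
    z: int = 2,
) -> list[GlycanFragment]:
    """Theoretical B and Y glycan fragments for a candidate assignment.

    Y ions are generated at charges 1..z; when the adduct is retained on Y
    ions (metal cations) an adducted copy of each Y ion is added. B ions
    are 1+ oxonium-type ions of bounded sub-compositions. An empty glycan
    yields Y0 only; a nonempty composition must contain HexNAc (N-glycan).
    """
    if glycan and glycan["HexNAc"] == 0:
        raise ValueError(f"{glycan} is not a valid N-glycan (no HexNAc)")
    frags: list[GlycanFragment] = []
    charges = range(1, max(z, 1) + 1)
    for sub in _y_subcompositions(glycan):
        label = f"Y:{sub}" if sub else "Y0"
        for c in charges:
            frags.append(
                GlycanFragment(sub, "Y", 0, c,
                               y_ion_mz(peptide_mass, sub, c), label)
            )
            if adduct.retained_on_y_ions and adduct.neutral_mass_shift:
                frags.append(
                    GlycanFragment(
                        sub, "Y", 0, c,
                        y_ion_mz(peptide_mass, sub, c,
                                 adduct.neutral_mass_shift),
                        label + f"+{adduct.name}",
                    )
                )
    for sub, losses in _b_subcompositions(glycan):
        label = f"B:{sub}" + ("-H2O" * losses)
        frags.append(
            GlycanFragment(sub, "B", losses, 1,
                           oxonium_mz(sub, losses, 1), label)
        )
    return frags


def _fragment_matched(
    s: Spectrum, mz: float, cfg: GlycoScoreConfig
) -> tuple[bool, float, float]:
    peaks = match_peaks(s, mz, cfg.frag_tol_ppm)
    if not peaks:
        return False, 0.0, 0.0
    floor = cfg.min_fragment_relative_intensity * s.base_peak_intensity
    best = max(peaks, key=lambda p: p.intensity)
    if best.intensity < floor:
        return False, 0.0, 0.0
    return True, best.mz, best.intensity


def glyco_score(
    s: Spectrum,
    peptide_mass: float,
    glycan: GlycanComposition,
    adduct: Adduct = NO_ADDUCT,
    cfg: GlycoScoreConfig = GlycoScoreConfig(),
    z: int | None = None,
) -> tuple[float, FragmentLedger]:
    """Score a candidate glycan assignment against observed B/Y ions.

    Each distinct expected fragment matched (at any charge) earns
    ``point_per_supporting_ion``. Penalties: each sialic type in the
    candidate with no matching sialic B ion observed; fucose in the
    candidate with no Fuc-containing B/Y matched; each catalogued
    non-sialic diagnostic ion observed that implies residues absent from
    the candidate. Observed sialic ions *not* in the candidate are free.
    """
    if z is None:
        z = s.precursor_charge
    ledger = FragmentLedger()
    frags = expected_fragments(peptide_mass, glycan, adduct, z)
    # isobaric expected fragments (e.g. Hex+NeuAc vs Fuc+NeuGc sub-glycans,
    # identical to the microdalton) must not each earn a point for the same
    # peak: group by (series, neutral fragment mass) and count groups.
    matched_groups: set[tuple[str, float]] = set()
    matched_mz: set[float] = set()
    fuc_supported = False
    matched_sialic: set[str] = set()
    for f in frags:
        (ledger.expected_b if f.series == "B" else ledger.expected_y).append(f)
        ok, pmz, pint = _fragment_matched(s, f.mz, cfg)
        if not ok:
            continue
        ledger.matched.append((f, pmz, pint))
        matched_mz.add(round(pmz, 4))
        if f.sub_composition["Fuc"]:
            fuc_supported = True
        for t in SIALIC_TOKENS:
            if f.series == "B" and f.sub_composition[t]:
                matched_sialic.add(t)
        neutral = f.mz * f.charge  # charge-independent group key
        matched_groups.add((f.series, round(neutral - f.charge * 1.00727646688, 3)))

    score = cfg.point_per_supporting_ion * len(matched_groups)

    for t in SIALIC_TOKENS:
        if glycan[t] > 0 and t not in matched_sialic:
            score += cfg.sialic_missing_penalty
            ledger.penalties[f"missing-{t}-ions"] = cfg.sialic_missing_penalty
    if glycan["Fuc"] > 0 and not fuc_supported:
        score += cfg.fucose_unsupported_penalty
        ledger.penalties["unsupported-Fuc"] = cfg.fucose_unsupported_penalty

    for ion in DIAGNOSTIC_IONS:
        if any(ion.residues[t] for t in SIALIC_TOKENS):
            continue  # sialic background is never contradicting
        if glycan.contains(ion.residues):
            continue  # consistent with the candidate
        ok, pmz, pint = _fragment_matched(s, ion.mz, cfg)
        if ok and round(pmz, 4) not in matched_mz:
            score += cfg.point_per_contradicting_ion
            ledger.contradicting.append((ion.label, pmz, pint))

    return score, ledger


# ---------------------------------------------------------------------------
# background-ion statistics

_HEXNACHEX = GlycanComposition.from_dict({"HexNAc": 1, "Hex": 1})
_HEXNAC1 = GlycanComposition.from_dict({"HexNAc": 1})
REARRANGEMENT_INTENSITY_FRACTION = 0.05  # of the Y1 intensity


def background_ion_stats(
    matches: Sequence,
    spectra: Sequence[Spectrum],
    frag_tol_ppm: float = 20.0,
) -> pd.DataFrame:
    """Tabulate how often catalogued B ions (and the Y+HexNAcHex
    rearrangement indicator) are observed, and observed-but-not-expected.

    Also sets ``rearrangement`` in each match's flags when its
    peptide+HexNAcHex Y peak exceeds 5% of the Y1 intensity.
    """
    by_key = {s.key: s for s in spectra}
    rows = []
    for ion in DIAGNOSTIC_IONS:
        observed = unexpected = 0
        for m in matches:
            s = by_key.get(m.spectrum)
            if s is None or not match_peaks(s, ion.mz, frag_tol_ppm):
                continue
            observed += 1
            if not m.glycan.contains(ion.residues):
                unexpected += 1
        rows.append((ion.label, round(ion.mz, 4), observed, unexpected))

    y_obs = y_unexp = 0
    for m in matches:
        s = by_key.get(m.spectrum)
        if s is None:
            continue
        pep_mass = m.peptide.neutral_mass
        rearr_int = 0.0
        y1_int = 0.0
        seen = False
        for c in range(1, s.precursor_charge + 1):
            hits = match_peaks(s, y_ion_mz(pep_mass, _HEXNACHEX, c), frag_tol_ppm)
            if hits:
                seen = True
                rearr_int = max(rearr_int, max(p.intensity for p in hits))
            y1 = match_peaks(s, y_ion_mz(pep_mass, _HEXNAC1, c), frag_tol_ppm)
            if y1:
                y1_int = max(y1_int, max(p.intensity for p in y1))
        if seen:
            y_obs += 1
            # an intact N-glycan cannot yield peptide+HexNAcHex: always a
            # rearrangement (or chance) product, i.e. never "expected"
            y_unexp += 1
            if y1_int > 0 and rearr_int > REARRANGEMENT_INTENSITY_FRACTION * y1_int:
                m.flags.add("rearrangement")
    rows.append(("Y+HexNAcHex", float("nan"), y_obs, y_unexp))

    return pd.DataFrame(
        rows, columns=["ion", "mz", "observed", "observed_not_expected"]
    )
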