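"""Peptide-first glycopeptide database search (workflow step 2).

Fully tryptic in-silico digestion with variable modifications, glycan
oxonium peak stripping, peptide b/y scoring with core-HexNAc retention on
glycosite-spanning fragments, precursor matching of peptide + glycan-set
masses (no adducts at this stage), and target-decoy FDR thresholding at
the unique-peptide and protein level.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pmass

from .chem import (
    MONOSACCHARIDES,
    PROTON,
    WATER,
    Adduct,
    GlycanComposition,
    NO_ADDUCT,
    find_nglyco_motifs,
    mz_from_neutral,
    neutral_from_mz,
    oxonium_strip_mz,
    y_ion_mz,
)
from .glycansets import default_glycan_set
from .msio import Spectrum, match_peaks

log = logging.getLogger(__name__)

HEXNAC_RESIDUE = MONOSACCHARIDES["HexNAc"].residue_mass

# variable modification deltas
OXIDATION = 15.9949146221
ACETYL = 42.0105646863
PYROGLU_Q = -17.0265491015  # Gln -> pyro-Glu, loss of NH3


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 20.0
    max_missed_cleavages: int = 3
    min_peptide_length: int = 5
    max_peptide_length: int = 60
    oxidation_m: bool = True
    pyroglu_nterm_q: bool = True
    protein_nterm_variants: bool = True  # Met removal and/or acetylation
    max_variable_mods_per_peptide: int = 2
    glycan_set: tuple[GlycanComposition, ...] | None = None  # None = default set
    fdr_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm < 0 or self.fragment_tol_ppm < 0:
            raise ValueError("tolerances must be >= 0")
        if not 0 < self.fdr_threshold < 1 and self.fdr_threshold != 0:
            raise ValueError("fdr_threshold must be in [0, 1)")

    def glycans(self) -> tuple[GlycanComposition, ...]:
        if self.glycan_set is None:
            return tuple(default_glycan_set())
        return self.glycan_set


Mod = tuple[int, str, float]  # (position, name, delta mass); -1 = N-term


@dataclass(frozen=True)
class PeptideCandidate:
    """A digested peptide with variable mods (glycan excluded)."""

    sequence: str
    mods: tuple[Mod, ...] = ()
    proteins: tuple[str, ...] = ()
    motif_positions: tuple[int, ...] = ()
    is_decoy: bool = False

    @property
    def neutral_mass(self) -> float:
        return _pmass.fast_mass(self.sequence) + sum(d for _, _, d in self.mods)

    @property
    def key(self) -> tuple[str, tuple[Mod, ...]]:
        return (self.sequence, self.mods)

    def mods_string(self) -> str:
        if not self.mods:
            return ""
        return ";".join(f"{name}@{pos}" for pos, name, _ in self.mods)


@dataclass
class GlycopeptideMatch:
    """One spectrum's glycopeptide assignment."""

    spectrum: tuple[str, str]
    peptide: PeptideCandidate
    glycan: GlycanComposition
    adduct: Adduct = NO_ADDUCT
    isotope_offset: int = 0
    peptide_score: float = 0.0
    glyco_score: float = float("nan")
    precursor_error_ppm: float = 0.0
    rt_min: float = 0.0
    precursor_mz: float = 0.0
    charge: int = 2
    flags: set[str] = field(default_factory=set)

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    def to_row(self) -> dict:
        return {
            "file": self.spectrum[0],
            "scan": self.spectrum[1],
            "rt_min": round(self.rt_min, 3),
            "precursor_mz": round(self.precursor_mz, 5),
            "charge": self.charge,
            "peptide": self.peptide.sequence,
            "mods": self.peptide.mods_string(),
            "proteins": ";".join(self.peptide.proteins),
            "glycan": str(self.glycan),
            "adduct": self.adduct.name,
            "isotope_offset": self.isotope_offset,
            "peptide_score": self.peptide_score,
            "glyco_score": self.glyco_score,
            "precursor_error_ppm": round(self.precursor_error_ppm, 3),
            "is_decoy": self.is_decoy,
            "flags": ";".join(sorted(self.flags)),
        }


# ---------------------------------------------------------------------------
# digestion


def _tryptic_segments(seq: str) -> list[tuple[int, int]]:
    """(start, end) of minimal tryptic segments: cleave after K/R not before P."""
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(seq)]
    return list(zip(starts, ends))


def digest(protein, params: SearchParams = SearchParams()) -> list[PeptideCandidate]:
    """All fully tryptic peptides of a protein with variable-mod variants.

    Missed cleavages 0..max; length bounds applied; protein N-terminal
    peptides expand into Met-removal/acetylation permutations; Oxidation(M)
    and N-terminal Gln->pyro-Glu variants enumerated up to the per-peptide
    variable-mod cap.
    """
    seq = protein.sequence
    segments = _tryptic_segments(seq)
    out: list[PeptideCandidate] = []
    for i in range(len(segments)):
        for j in range(i, min(i + params.max_missed_cleavages + 1, len(segments))):
            start, end = segments[i][0], segments[j][1]
            pep = seq[start:end]
            forms: list[tuple[str, tuple[Mod, ...]]] = [(pep, ())]
            if start == 0 and params.protein_nterm_variants:
                forms.append((pep, ((-1, "Acetyl", ACETYL),)))
                if pep.startswith("M") and len(pep) > 1:
                    forms.append((pep[1:], ()))
                    forms.append((pep[1:], ((-1, "Acetyl", ACETYL),)))
            for base, base_mods in forms:
                if not params.min_peptide_length <= len(base) <= params.max_peptide_length:
                    continue
                out.extend(
                    PeptideCandidate(
                        base,
                        mods,
                        (protein.accession,),
                        tuple(find_nglyco_motifs(base)),
                        protein.is_decoy,
                    )
                    for mods in _mod_variants(base, base_mods, params)
                )
    return out


def _mod_variants(
    pep: str, base_mods: tuple[Mod, ...], params: SearchParams
) -> list[tuple[Mod, ...]]:
    budget = params.max_variable_mods_per_peptide - len(base_mods)
    variants: list[tuple[Mod, ...]] = [base_mods]
    if params.pyroglu_nterm_q and pep.startswith("Q") and budget >= 1:
        variants.append(base_mods + ((0, "Gln->pyro-Glu", PYROGLU_Q),))
    if params.oxidation_m:
        mpos = [i for i, aa in enumerate(pep) if aa == "M"]
        extra = []
        for mods in variants:
            room = params.max_variable_mods_per_peptide - len(mods)
            for k in range(1, min(room, len(mpos)) + 1):
                for combo in combinations(mpos, k):
                    extra.append(
                        mods + tuple((p, "Oxidation", OXIDATION) for p in combo)
                    )
        variants.extend(extra)
    return [tuple(sorted(m)) for m in variants]


def build_peptide_index(
    proteins: Sequence, params: SearchParams, glyco_only: bool = True
) -> list[PeptideCandidate]:
    """Digest all proteins; merge duplicate (sequence, mods) across proteins."""
    merged: dict = {}
    for prot in proteins:
        for cand in digest(prot, params):
            if glyco_only and not cand.motif_positions:
                continue
            prev = merged.get(cand.key)
            if prev is None:
                merged[cand.key] = cand
            elif cand.proteins[0] not in prev.proteins:
                merged[cand.key] = PeptideCandidate(
                    prev.sequence,
                    prev.mods,
                    prev.proteins + cand.proteins,
                    prev.motif_positions,
                    prev.is_decoy and cand.is_decoy,
                )
    return sorted(merged.values(), key=lambda c: c.neutral_mass)


# ---------------------------------------------------------------------------
# spectrum preprocessing and peptide scoring


def strip_oxonium_peaks(s: Spectrum, frag_tol_ppm: float = 20.0) -> Spectrum:
    """Remove peaks matching any catalogued glycan oxonium/B ion (1+).

    Returns a new Spectrum; the input is untouched. Idempotent.
    """
    if not len(s.mz):
        return s
    drop = np.zeros(len(s.mz), dtype=bool)
    for mz in oxonium_strip_mz():
        half = mz * frag_tol_ppm * 1e-6
        lo = np.searchsorted(s.mz, mz - half, side="left")
        hi = np.searchsorted(s.mz, mz + half, side="right")
        drop[lo:hi] = True
    if not drop.any():
        return s
    return s.without_peaks(drop)


def _fragment_masses(cand: PeptideCandidate, glycosite: int | None) -> list[tuple[str, float]]:
    """Neutral masses of b/y fragments; glycosite-spanning ones carry +HexNAc."""
    seq = cand.sequence
    n = len(seq)
    aa = [_pmass.fast_mass(a) - WATER for a in seq]
    delta_at = {}
    nterm_delta = 0.0
    for pos, _, d in cand.mods:
        if pos < 0:
            nterm_delta += d
        else:
            delta_at[pos] = delta_at.get(pos, 0.0) + d
    prefix = np.cumsum([aa[i] + delta_at.get(i, 0.0) for i in range(n)])
    total = prefix[-1] + WATER + nterm_delta
    frags = []
    for i in range(1, n):  # b_i / y_(n-i)
        b = prefix[i - 1] + nterm_delta
        y = total - b
        if glycosite is not None:
            if glycosite < i:
                b += HEXNAC_RESIDUE
            else:
                y += HEXNAC_RESIDUE
        frags.append((f"b{i}", b))
        frags.append((f"y{n - i}", y))
    return frags


def score_peptide(
    s: Spectrum,
    cand: PeptideCandidate,
    glycan_on_motif: bool = True,
    frag_tol_ppm: float = 20.0,
) -> tuple[float, float]:
    """Count matched b/y fragments; returns (score, matched intensity sum).

    Fragments containing the glycosylated Asn (the first sequon when
    ``glycan_on_motif``) carry the retained core HexNAc. Fragment charges
    1..max(1, precursor charge − 1) are probed; a fragment matched at any
    charge counts once. A Y1 bonus point is added when the peptide+HexNAc
    Y1 ion is present at any charge up to the precursor charge.
    """
    glycosite = cand.motif_positions[0] if (glycan_on_motif and cand.motif_positions) else None
    max_fc = max(1, s.precursor_charge - 1)
    score = 0.0
    intensity = 0.0
    for _, neutral in _fragment_masses(cand, glycosite):
        best = 0.0
        for c in range(1, max_fc + 1):
            hits = match_peaks(s, mz_from_neutral(neutral, c), frag_tol_ppm)
            if hits:
                best = max(best, max(p.intensity for p in hits))
        if best > 0:
            score += 1.0
            intensity += best
    if glycosite is not None:
        y1 = cand.neutral_mass + HEXNAC_RESIDUE
        for c in range(1, s.precursor_charge + 1):
            if match_peaks(s, mz_from_neutral(y1, c), frag_tol_ppm):
                score += 1.0  # Y1 bonus
                break
    return score, intensity


# ---------------------------------------------------------------------------
# the search proper


def search(
    spectra: Sequence[Spectrum],
    proteins: Sequence,
    params: SearchParams = SearchParams(),
    subset_index: Iterable[tuple[str, str]] | None = None,
) -> list[GlycopeptideMatch]:
    """Peptide-first search of (oxonium-filtered) spectra.

    For each spectrum, candidates are sequon-containing peptides whose
    neutral mass plus some glycan-set mass matches the precursor within
    tolerance; no adducts and no isotope offsets at this stage. The best
    peptide by (matched-ion score, matched intensity) is reported with the
    glycan matched by mass alone.
    """
    glycans = params.glycans()
    if not glycans:
        raise ValueError("empty glycan set")
    index = build_peptide_index(proteins, params)
    masses = np.array([c.neutral_mass for c in index])
    allowed = set(subset_index) if subset_index is not None else None

    matches: list[GlycopeptideMatch] = []
    for s in spectra:
        if allowed is not None and s.key not in allowed:
            continue
        neutral = neutral_from_mz(s.precursor_mz, s.precursor_charge)
        tol = neutral * params.precursor_tol_ppm * 1e-6
        stripped = strip_oxonium_peaks(s, params.fragment_tol_ppm)
        best = None
        for g in glycans:
            target = neutral - g.mass
            if target <= 0:
                continue
            lo = int(np.searchsorted(masses, target - tol, side="left"))
            hi = int(np.searchsorted(masses, target + tol, side="right"))
            for k in range(lo, hi):
                cand = index[k]
                score, inten = score_peptide(
                    stripped, cand, True, params.fragment_tol_ppm
                )
                err_ppm = (neutral - cand.neutral_mass - g.mass) / neutral * 1e6
                entry = (score, inten, -abs(err_ppm), cand, g, err_ppm)
                if best is None or entry[:3] > best[:3]:
                    best = entry
        if best is not None:
            score, inten, _, cand, g, err_ppm = best
            matches.append(
                GlycopeptideMatch(
                    spectrum=s.key,
                    peptide=cand,
                    glycan=g,
                    peptide_score=score,
                    precursor_error_ppm=err_ppm,
                    rt_min=s.retention_time,
                    precursor_mz=s.precursor_mz,
                    charge=s.precursor_charge,
                )
            )
    log.info("search: %d/%d spectra matched", len(matches), len(spectra))
    return matches


# ---------------------------------------------------------------------------
# target-decoy FDR


def _best_threshold(scored: list[tuple[float, bool]], fdr: float) -> float:
    """Lowest score threshold whose decoy/target ratio stays <= fdr.

    ``scored``: (score, is_decoy) per unit (peptide or protein). Scans all
    observed cut points; returns the threshold accepting the most targets.
    """
    scored = sorted(scored, reverse=True)
    best_t = float("inf")
    best_n = -1
    targets = decoys = 0
    i = 0
    while i < len(scored):
        t = scored[i][0]
        while i < len(scored) and scored[i][0] == t:
            if scored[i][1]:
                decoys += 1
            else:
                targets += 1
            i += 1
        rate = decoys / targets if targets else float("inf")
        if rate <= fdr and targets > best_n:
            best_n = targets
            best_t = t
    return best_t


def threshold_fdr(
    matches: Sequence[GlycopeptideMatch],
    params: SearchParams = SearchParams(),
    allow_no_decoys: bool = False,
) -> list[GlycopeptideMatch]:
    """Threshold matches at the configured FDR, unique-peptide then protein level.

    Peptide score = best match score per unique (sequence, mods); protein
    score = best peptide score per accession. Returns the matches (targets
    and any decoys) passing both thresholds. Raises if no decoys are
    present (the estimate would be undefined) unless ``allow_no_decoys``
    — then every match is accepted (the empirical decoy rate is zero at
    any threshold).
    """
    if not any(m.is_decoy for m in matches):
        if allow_no_decoys:
            return list(matches)
        raise ValueError("no decoy matches present: FDR is undefined")
    fdr = params.fdr_threshold

    pep_best: dict = {}
    for m in matches:
        k = m.peptide.key
        if k not in pep_best or m.peptide_score > pep_best[k][0]:
            pep_best[k] = (m.peptide_score, m.is_decoy)
    pep_t = _best_threshold(list(pep_best.values()), fdr)

    prot_best: dict = {}
    for m in matches:
        if pep_best[m.peptide.key][0] < pep_t:
            continue
        for acc in m.peptide.proteins:
            sc = prot_best.get(acc)
            if sc is None or m.peptide_score > sc[0]:
                prot_best[acc] = (m.peptide_score, m.is_decoy)
    prot_t = _best_threshold(list(prot_best.values()), fdr)

    accepted = [
        m
        for m in matches
        if pep_best[m.peptide.key][0] >= pep_t
        and any(prot_best.get(a, (-1,))[0] >= prot_t for a in m.peptide.proteins)
    ]
    return accepted
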