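"""Y1-ion-driven glycoform expansion (workflow step 3).

Takes the confidently identified glycopeptide sequences (seeds) from the
database search and scans all oxonium-filtered spectra for their Y0/Y1/Y2
ions, enumerating every (glycan, adduct, isotope offset) combination that
explains the precursor mass, scoring each surviving candidate for peptide
and glycan fragments, and deduplicating to one assignment per spectrum.

This is where adducts enter: ammonium shifts the precursor only, metal
cations additionally ride on glycan Y fragments. Near-ties between
same-mass candidates (the 0.994 Da ammonium/isotope and 0.011 Da
NeuGc+NH4 vs 2×Hex isobars) are reported with an ambiguity flag rather
than silently picking one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ISOTOPE_SPACING,
    MONOSACCHARIDES,
    Adduct,
    GlycanComposition,
    NO_ADDUCT,
    get_adduct,
    mz_from_neutral,
    neutral_from_mz,
)
from .msio import Spectrum, match_peaks
from .scoring import GlycoScoreConfig, glyco_score
from .search import (
    GlycopeptideMatch,
    PeptideCandidate,
    SearchParams,
    score_peptide,
    strip_oxonium_peaks,
)

log = logging.getLogger(__name__)

HEXNAC_RESIDUE = MONOSACCHARIDES["HexNAc"].residue_mass
AMBIGUITY_MARGIN = 1.0  # glyco-score gap at or below which the top is flagged


@dataclass(frozen=True)
class YSearchParams:
    require_series: frozenset[str] = frozenset({"Y1"})
    y_tol_ppm: float = 20.0
    min_peptide_score: float = 0.0
    min_glyco_score: float = 5.0
    adducts: tuple[Adduct, ...] = (
        NO_ADDUCT,
        get_adduct("NH4"),
        get_adduct("Fe[III]"),
        get_adduct("Al[III]"),
    )
    isotope_offsets: tuple[int, ...] = (-1, 0, 1)
    isotope_spacing: float = ISOTOPE_SPACING
    precursor_tol_ppm: float = 5.0
    score_config: GlycoScoreConfig = GlycoScoreConfig()

    def __post_init__(self) -> None:
        if not self.require_series <= {"Y0", "Y1", "Y2"}:
            raise ValueError("require_series must be a subset of {Y0, Y1, Y2}")
        if any(abs(o) > 2 for o in self.isotope_offsets):
            raise ValueError("isotope offsets limited to -2..+2")


@dataclass(frozen=True)
class SeedPeptide:
    """A confidently identified glycopeptide sequence to expand."""

    peptide: PeptideCandidate  # sequence + non-glycan mods
    peptide_count_for_protein: int = 1
    mean_rt: float = 0.0
    rt_spread: float = 0.0

    @property
    def neutral_mass(self) -> float:
        return self.peptide.neutral_mass


@dataclass(frozen=True)
class Candidate:
    glycan: GlycanComposition
    adduct: Adduct
    isotope_offset: int
    error_ppm: float


def build_seed_list(accepted: Sequence[GlycopeptideMatch]) -> list[SeedPeptide]:
    """Unique (sequence, non-glycan mods) seeds from FDR-accepted matches.

    Decoy matches are skipped. Retention-time mean and spread aggregate
    over the glycoforms observed for each seed.
    """
    if not accepted:
        raise ValueError("no accepted matches to build seeds from")
    groups: dict = {}
    for m in accepted:
        if m.is_decoy:
            continue
        groups.setdefault(m.peptide.key, []).append(m)
    seeds = []
    prot_counts: dict[str, set] = {}
    for key, ms in groups.items():
        for acc in ms[0].peptide.proteins:
            prot_counts.setdefault(acc, set()).add(key)
    for key, ms in sorted(groups.items()):
        rts = [m.rt_min for m in ms]
        pep = ms[0].peptide
        seeds.append(
            SeedPeptide(
                peptide=pep,
                peptide_count_for_protein=max(
                    len(prot_counts[a]) for a in pep.proteins
                ),
                mean_rt=float(np.mean(rts)),
                rt_spread=float(max(rts) - min(rts)),
            )
        )
    return seeds


def enumerate_candidates(
    precursor_neutral: float,
    seed: SeedPeptide,
    glycans: Sequence[GlycanComposition],
    params: YSearchParams = YSearchParams(),
) -> list[Candidate]:
    """All (glycan, adduct, offset) explaining the precursor mass.

    A combination qualifies when
    ``|precursor − offset×spacing − (peptide + glycan + adduct)|`` is
    within the precursor tolerance (ppm of the precursor mass).
    """
    out: list[Candidate] = []
    tol = precursor_neutral * params.precursor_tol_ppm * 1e-6
    gmass = np.array([g.mass for g in glycans])
    for adduct in params.adducts:
        base = seed.neutral_mass + adduct.neutral_mass_shift
        for off in params.isotope_offsets:
            target = precursor_neutral - off * params.isotope_spacing
            err = target - (base + gmass)
            for idx in np.nonzero(np.abs(err) <= tol)[0]:
                out.append(
                    Candidate(
                        glycans[int(idx)],
                        adduct,
                        off,
                        float(err[idx] / precursor_neutral * 1e6),
                    )
                )
    return out


@dataclass(frozen=True)
class YMatch:
    series: str  # Y0 | Y1 | Y2
    charge: int
    adducted: bool
    mz: float
    intensity: float


def detect_y_ions(
    s: Spectrum,
    seed: SeedPeptide,
    candidate: Candidate,
    params: YSearchParams = YSearchParams(),
) -> list[YMatch]:
    """Match Y0/Y1/Y2 ions (peptide + 0-2 core HexNAc) at charges 1..z.

    For metal adducts retained on Y ions both the plain and the adducted
    m/z are probed; matches are annotated accordingly.
    """
    pep = seed.neutral_mass
    shifts = [(False, 0.0)]
    if candidate.adduct.retained_on_y_ions and candidate.adduct.neutral_mass_shift:
        shifts.append((True, candidate.adduct.neutral_mass_shift))
    n_hexnac = candidate.glycan["HexNAc"]
    out: list[YMatch] = []
    for k, series in ((0, "Y0"), (1, "Y1"), (2, "Y2")):
        if k > n_hexnac:
            continue
        neutral = pep + k * HEXNAC_RESIDUE
        for adducted, shift in shifts:
            for c in range(1, s.precursor_charge + 1):
                hits = match_peaks(s, mz_from_neutral(neutral + shift, c),
                                   params.y_tol_ppm)
                if hits:
                    best = max(hits, key=lambda p: p.intensity)
                    out.append(YMatch(series, c, adducted, best.mz, best.intensity))
    return out


def candidate_survives(y_matches: Sequence[YMatch], params: YSearchParams) -> bool:
    present = {m.series for m in y_matches}
    return params.require_series <= present


def assign_best(
    s: Spectrum,
    seed: SeedPeptide,
    candidates: Sequence[Candidate],
    params: YSearchParams = YSearchParams(),
    fragment_tol_ppm: float = 20.0,
) -> GlycopeptideMatch | None:
    """Score surviving candidates and return the best, or None.

    Ranking: glyco score, then peptide score, then fewest |offset|, then
    no-adduct before adduct, then lexicographic composition. The result
    must meet both score thresholds. A runner-up within one glyco-score
    point sets the ``ambiguous`` flag naming it.
    """
    stripped = strip_oxonium_peaks(s, fragment_tol_ppm)
    pep_score, _ = score_peptide(stripped, seed.peptide, True, fragment_tol_ppm)
    if pep_score < params.min_peptide_score:
        return None
    scored = []
    for cand in candidates:
        y = detect_y_ions(s, seed, cand, params)
        if not candidate_survives(y, params):
            continue
        gscore, ledger = glyco_score(
            s, seed.neutral_mass, cand.glycan, cand.adduct,
            params.score_config, s.precursor_charge,
        )
        scored.append((
            (-gscore, -pep_score, abs(cand.isotope_offset),
             0 if cand.adduct is NO_ADDUCT or cand.adduct.name == "none" else 1,
             str(cand.glycan)),
            gscore, cand,
        ))
    if not scored:
        return None
    scored.sort(key=lambda t: t[0])
    _, gscore, cand = scored[0]
    if gscore < params.min_glyco_score:
        return None
    flags: set[str] = set()
    if len(scored) > 1:
        runner_score, runner = scored[1][1], scored[1][2]
        if gscore - runner_score <= AMBIGUITY_MARGIN:
            flags.add(
                f"ambiguous:{runner.glycan}+{runner.adduct.name}@{runner.isotope_offset:+d}"
            )
    return GlycopeptideMatch(
        spectrum=s.key,
        peptide=seed.peptide,
        glycan=cand.glycan,
        adduct=cand.adduct,
        isotope_offset=cand.isotope_offset,
        peptide_score=pep_score,
        glyco_score=gscore,
        precursor_error_ppm=cand.error_ppm,
        rt_min=s.retention_time,
        precursor_mz=s.precursor_mz,
        charge=s.precursor_charge,
        flags=flags,
    )


def expand_glycoforms(
    spectra: Sequence[Spectrum],
    seeds: Sequence[SeedPeptide],
    glycans: Sequence[GlycanComposition],
    params: YSearchParams = YSearchParams(),
    subset_index: Iterable[tuple[str, str]] | None = None,
) -> list[GlycopeptideMatch]:
    """Run the Y1 expansion over all spectra and seeds, then deduplicate.

    For each spectrum every seed whose candidate list is non-empty and
    whose required Y series is present is scored; the per-spectrum winner
    is kept by the dedupe sort order.
    """
    allowed = set(subset_index) if subset_index is not None else None
    # every surviving candidate must show the required Y series; when Y1 is
    # required a cheap presence probe (plain and retained-adduct-shifted)
    # prunes (spectrum, seed) pairs before any scoring
    y1_required = "Y1" in params.require_series
    probe_shifts = [0.0] + [
        a.neutral_mass_shift for a in params.adducts if a.retained_on_y_ions
    ]
    matches: list[GlycopeptideMatch] = []
    for s in spectra:
        if allowed is not None and s.key not in allowed:
            continue
        neutral = neutral_from_mz(s.precursor_mz, s.precursor_charge)
        for seed in seeds:
            if y1_required:
                y1 = seed.neutral_mass + HEXNAC_RESIDUE
                if not any(
                    match_peaks(s, mz_from_neutral(y1 + sh, c), params.y_tol_ppm)
                    for sh in probe_shifts
                    for c in range(1, s.precursor_charge + 1)
                ):
                    continue
            cands = enumerate_candidates(neutral, seed, glycans, params)
            if not cands:
                continue
            m = assign_best(s, seed, cands, params)
            if m is not None:
                matches.append(m)
    deduped = dedupe_spectral_ids(matches)
    log.info(
        "glycoform expansion: %d assignments over %d spectra", len(deduped), len(spectra)
    )
    return deduped


def dedupe_spectral_ids(
    matches: Sequence[GlycopeptideMatch],
) -> list[GlycopeptideMatch]:
    """One match per (file, scan): sort by file, scan, glyco score desc,
    peptide score desc, and keep the first."""
    ordered = sorted(
        matches,
        key=lambda m: (
            m.spectrum[0],
            m.spectrum[1],
            -(m.glyco_score if m.glyco_score == m.glyco_score else -1e9),
            -m.peptide_score,
        ),
    )
    seen: set[tuple[str, str]] = set()
    out = []
    for m in ordered:
        if m.spectrum not in seen:
            seen.add(m.spectrum)
            out.append(m)
    return out
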