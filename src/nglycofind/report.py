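"""Result summarization and implausible-adduct FDR estimation.

Spectral matches are collapsed to unique glycopeptides (peptide + glycan
with the adduct stripped) and to glycosylated peptide sequences. The
error rate of the whole assignment process is estimated with the decoy
adduct device: an adduct believed absent from the sample (aluminum by
default) is searched alongside the real ones; every match to it is a
random match, and a similar number of random matches is assumed in the
no-adduct class and in each plausible adduct class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import Adduct
from .search import GlycopeptideMatch


@dataclass
class SummaryCounts:
    spectral_ids_total: int = 0
    spectral_ids_by_adduct: dict[str, int] = field(default_factory=dict)
    unique_glycopeptides: int = 0
    glycosylated_peptide_sequences: int = 0
    glycoforms_per_peptide_histogram: dict[int, int] = field(default_factory=dict)

    def mean_glycoforms_per_sequence(self) -> float:
        n = sum(self.glycoforms_per_peptide_histogram.values())
        if not n:
            return 0.0
        return (
            sum(k * v for k, v in self.glycoforms_per_peptide_histogram.items()) / n
        )


def _unique_key(m: GlycopeptideMatch):
    """Adduct-stripped unique-glycopeptide key."""
    return (m.peptide.sequence, m.peptide.mods, str(m.glycan))


def collapse_unique(matches: Sequence[GlycopeptideMatch]) -> SummaryCounts:
    """Collapse deduplicated spectral matches to unique glycopeptides.

    The adduct is removed from the assignment before collapsing, so a
    glycopeptide seen both protonated and ammoniated counts once.
    """
    by_adduct = Counter(m.adduct.name for m in matches)
    uniques = {_unique_key(m) for m in matches}
    sequences = {k[0] for k in uniques}
    glycoforms = Counter(k[0] for k in uniques)
    histogram = Counter(glycoforms.values())
    return SummaryCounts(
        spectral_ids_total=len(matches),
        spectral_ids_by_adduct=dict(sorted(by_adduct.items())),
        unique_glycopeptides=len(uniques),
        glycosylated_peptide_sequences=len(sequences),
        glycoforms_per_peptide_histogram=dict(sorted(histogram.items())),
    )


def adduct_fdr_from_counts(
    decoy_count: int, class_counts: Mapping[str, int]
) -> tuple[dict[str, float], float]:
    """Closed-form decoy-adduct FDR from spectral counts.

    ``class_counts`` maps each *accepted* class (the no-adduct class and
    each plausible adduct searched) to its spectral-match count. Assuming
    the decoy-adduct count of random matches recurs in every accepted
    class: per-class FDR = d / n_class; overall FDR =
    d × n_classes / total.
    """
    if any(n < 0 for n in class_counts.values()) or decoy_count < 0:
        raise ValueError("counts must be non-negative")
    per_class = {
        name: (decoy_count / n if n else 0.0) for name, n in class_counts.items()
    }
    total = sum(class_counts.values())
    overall = decoy_count * len(class_counts) / total if total else 0.0
    return per_class, overall


def estimate_adduct_fdr(
    matches: Sequence[GlycopeptideMatch],
    decoy_adduct: Adduct,
    searched_adducts: Sequence[Adduct] | None = None,
) -> tuple[dict[str, float], float, list[GlycopeptideMatch]]:
    """Estimate per-class and overall FDR; drop decoy-adduct matches.

    Accepted classes are the no-adduct class plus every *plausible*
    searched adduct (from ``searched_adducts`` when given, else the
    adducts observed in the matches). Returns (per-class FDR, overall
    FDR, matches with the decoy-adduct assignments removed).
    """
    if decoy_adduct.plausible:
        raise ValueError(f"{decoy_adduct.name} is not flagged as a decoy adduct")
    names = {m.adduct.name for m in matches}
    if searched_adducts is not None:
        names |= {a.name for a in searched_adducts if a.plausible}
        if decoy_adduct.name not in {a.name for a in searched_adducts}:
            raise ValueError(
                f"decoy adduct {decoy_adduct.name} was not part of the search"
            )
    accepted_classes = sorted(
        n for n in names | {"none"} if n != decoy_adduct.name
    )
    counts = Counter(m.adduct.name for m in matches)
    d = counts.get(decoy_adduct.name, 0)
    class_counts = {n: counts.get(n, 0) for n in accepted_classes}
    per_class, overall = adduct_fdr_from_counts(d, class_counts)
    kept = [m for m in matches if m.adduct.name != decoy_adduct.name]
    return per_class, overall, kept


def flag_unsupported_adducts(
    matches: Sequence[GlycopeptideMatch],
) -> list[GlycopeptideMatch]:
    """Warn on adducted matches never seen fully protonated.

    Adducts of a glycopeptide are nearly always lower-intensity satellites
    of the protonated form, so an adducted assignment whose (peptide,
    glycan) never appears without an adduct is almost certainly wrong.
    Adds the ``no-protonated-support`` flag in place and returns the list.
    """
    protonated = {_unique_key(m) for m in matches if m.adduct.name == "none"}
    for m in matches:
        if m.adduct.name != "none" and _unique_key(m) not in protonated:
            m.flags.add("no-protonated-support")
    return list(matches)
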