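"""Reading and writing the formats the pipeline touches.

MGF peak lists (input, via pyteomics), FASTA protein databases with
sequence-randomized decoy generation (via pyteomics), and the
tab-separated glycopeptide result report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mgf as _pmgf


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum; peak arrays are kept sorted by m/z."""

    source_file: str
    scan_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_file, self.scan_id)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0

    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def without_peaks(self, drop: np.ndarray) -> "Spectrum":
        """Copy of the spectrum with a boolean mask of peaks removed."""
        keep = ~drop
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"sequence for {self.accession} must be uppercase")


# ---------------------------------------------------------------------------
# MGF


def _scan_from_title(title: str | None, ordinal: int) -> str:
    if title:
        for token in title.replace(",", " ").split():
            if token.startswith("scan="):
                return token[5:]
        return title.strip()
    return str(ordinal)


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF peak-list file into Spectrum objects.

    Scan ids come from the TITLE (a ``scan=N`` token if present, else the
    whole title), falling back to the block ordinal. RTINSECONDS is
    converted to minutes. Peaks are re-sorted ascending if needed.
    """
    path = str(path)
    name = Path(path).name
    spectra: list[Spectrum] = []
    with _pmgf.MGF(path) as reader:
        for ordinal, block in enumerate(reader, start=1):
            params = block["params"]
            if "pepmass" not in params:
                raise ValueError(f"block {ordinal} of {name}: missing PEPMASS")
            try:
                pepmass = params["pepmass"][0]
                charge = int(params["charge"][0]) if "charge" in params else 1
                rt_s = float(params.get("rtinseconds", 0.0))
                spectra.append(
                    Spectrum(
                        source_file=name,
                        scan_id=_scan_from_title(params.get("title"), ordinal),
                        precursor_mz=float(pepmass),
                        precursor_charge=abs(charge),
                        retention_time=rt_s / 60.0,
                        mz=block["m/z array"],
                        intensity=block["intensity array"],
                    )
                )
            except (TypeError, ValueError, KeyError) as exc:
                raise ValueError(f"malformed MGF block {ordinal} of {name}: {exc}")
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF with fixed formatting (byte-deterministic)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=scan={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            fh.write(f"RTINSECONDS={s.retention_time * 60.0:.3f}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.5f} {i:.2f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# FASTA

DECOY_PREFIX = "DECOY_"


def read_fasta(path, decoy_mode: str = "none", seed: int = 0) -> list[ProteinEntry]:
    """Read a protein FASTA; optionally append sequence-randomized decoys.

    With ``decoy_mode="randomized"`` each target yields one extra entry
    whose sequence is a seeded uniform within-protein shuffle (length and
    composition preserved) and whose accession carries ``DECOY_``.
    """
    if decoy_mode not in ("none", "randomized"):
        raise ValueError(f"unknown decoy_mode {decoy_mode!r}")
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    with _pfasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            acc = header.split()[0]
            desc = header[len(acc):].strip()
            if acc in seen:
                raise ValueError(f"duplicate accession {acc!r}")
            seen.add(acc)
            entries.append(ProteinEntry(acc, desc, seq.upper(), is_decoy=False))
    if not entries:
        raise ValueError(f"no FASTA entries in {path}")
    if decoy_mode == "randomized":
        rng = np.random.default_rng(seed)
        decoys = []
        for e in entries:
            letters = np.array(list(e.sequence))
            rng.shuffle(letters)
            decoys.append(
                ProteinEntry(
                    DECOY_PREFIX + e.accession,
                    "randomized decoy of " + e.accession,
                    "".join(letters),
                    is_decoy=True,
                )
            )
        entries = entries + decoys
    return entries


def write_fasta(entries: Sequence[ProteinEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = e.accession + ((" " + e.description) if e.description else "")
            fh.write(f">{header}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# peak matching


def match_peaks(s: Spectrum, target_mz: float, tol_ppm: float) -> list[Peak]:
    """All peaks with |mz − target| ≤ target × tol_ppm × 1e-6 (binary search)."""
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    half = target_mz * tol_ppm * 1e-6
    lo = int(np.searchsorted(s.mz, target_mz - half, side="left"))
    hi = int(np.searchsorted(s.mz, target_mz + half, side="right"))
    return [Peak(float(s.mz[i]), float(s.intensity[i])) for i in range(lo, hi)]


def has_peak(s: Spectrum, target_mz: float, tol_ppm: float,
             min_relative_intensity: float = 0.0) -> bool:
    peaks = match_peaks(s, target_mz, tol_ppm)
    if not peaks:
        return False
    if min_relative_intensity <= 0:
        return True
    floor = min_relative_intensity * s.base_peak_intensity
    return any(p.intensity >= floor for p in peaks)


# ---------------------------------------------------------------------------
# results TSV

RESULT_COLUMNS = [
    "file",
    "scan",
    "rt_min",
    "precursor_mz",
    "charge",
    "peptide",
    "mods",
    "proteins",
    "glycan",
    "adduct",
    "isotope_offset",
    "peptide_score",
    "glyco_score",
    "precursor_error_ppm",
    "is_decoy",
    "flags",
]


def write_results(matches, path) -> None:
    """Write GlycopeptideMatch rows as a fixed-column TSV report."""
    rows = [m.to_row() for m in matches]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"scan": str, "mods": str, "flags": str},
        keep_default_na=False, na_values=[],
    )
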