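"""Oxonium-ion spectral filtering (workflow step 1).

Selects probable glycopeptide spectra by requiring diagnostic low-mass
glycan oxonium peaks — by default the HexNAc oxonium ion at m/z 204.087
within 20 ppm, with no intensity floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .chem import HEXNAC_204
from .msio import Spectrum, has_peak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Which diagnostic peaks a spectrum must contain to pass.

    ``mode="any"`` passes a spectrum containing at least one required ion;
    ``mode="all"`` requires every one. ``min_relative_intensity`` is a
    fraction of the base peak in [0, 1].
    """

    required_mz: tuple[float, ...] = (HEXNAC_204,)
    tol_ppm: float = 20.0
    min_relative_intensity: float = 0.0
    mode: str = "all"

    def __post_init__(self) -> None:
        if self.tol_ppm < 0:
            raise ValueError("tol_ppm must be >= 0")
        if not 0.0 <= self.min_relative_intensity <= 1.0:
            raise ValueError("min_relative_intensity must be in [0, 1]")
        if self.mode not in ("any", "all"):
            raise ValueError(f"unknown mode {self.mode!r}")


def spectrum_passes(s: Spectrum, spec: FilterSpec) -> bool:
    hits = (
        has_peak(s, mz, spec.tol_ppm, spec.min_relative_intensity)
        for mz in spec.required_mz
    )
    return any(hits) if spec.mode == "any" else all(hits)


def filter_spectra(
    spectra: Sequence[Spectrum], spec: FilterSpec = FilterSpec()
) -> list[tuple[str, str]]:
    """Subset index of spectra containing the required diagnostic peaks.

    Returns (file, scan) keys in input order. Raises on an empty required
    ion list (the filter would be vacuous).
    """
    if not spec.required_mz:
        raise ValueError("FilterSpec.required_mz is empty: filter would be vacuous")
    index = [s.key for s in spectra if spectrum_passes(s, spec)]
    if spectra:
        log.info(
            "oxonium filter: %d/%d spectra pass (%.1f%%)",
            len(index), len(spectra), 100.0 * len(index) / len(spectra),
        )
    return index


def write_index(index: Sequence[tuple[str, str]], path) -> None:
    """Two-column subset index file (file, scan)."""
    with open(path, "w") as fh:
        fh.write("file\tscan\n")
        for f, scan in index:
            fh.write(f"{f}\t{scan}\n")


def read_index(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f, scan = line.rstrip("\n").split("\t")
            out.append((f, scan))
    return out
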