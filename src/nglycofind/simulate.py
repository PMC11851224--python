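"""Deterministic synthetic stepped-HCD glycopeptide datasets.

Generates a protein FASTA, an MGF of centroided MS/MS spectra and a truth
table so every pipeline stage is testable without external downloads.
Spectra emulate the merged peak lists a stepped-collision-energy
acquisition produces: peptide b/y ions with the core HexNAc retained on
glycosite-spanning fragments, the glycan Y ladder, B/oxonium ions,
ubiquitous background oxonium contamination, occasional
peptide+HexNAcHex rearrangement peaks (at under 5% of the Y1 intensity),
ammonium/metal adduct populations (metals shifting the glycan Y ions),
uniform noise peaks, and ppm-scale mass jitter.

What it does not model: isotope envelopes (monoisotopic sticks only; the
±1-isotope mechanism is exercised through explicit precursor offsets),
chromatographic elution beyond a per-peptide retention time, and
co-isolation chimera structure beyond the oxonium background bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    ISOTOPE_SPACING,
    GlycanComposition,
    NO_ADDUCT,
    get_adduct,
    mz_from_neutral,
    oxonium_mz,
    peptide_mass,
    find_nglyco_motifs,
    MONOSACCHARIDES,
    WATER,
)
from .msio import ProteinEntry, Spectrum, write_fasta, write_mgf

HEXNAC = MONOSACCHARIDES["HexNAc"].residue_mass
_C = GlycanComposition.parse

#: default glycan population: oligomannose-rich with sialylated biantennary
#: complex forms and minor phospho/fucosylated species, echoing a mammalian
#: liver glycopeptide enrichment.
DEFAULT_GLYCAN_FREQUENCY: dict[str, float] = {
    "HexNAc2Hex9": 0.16,
    "HexNAc2Hex8": 0.11,
    "HexNAc2Hex6": 0.09,
    "HexNAc2Hex5": 0.08,
    "HexNAc4Hex5NeuGc2": 0.12,
    "HexNAc4Hex5NeuAc2": 0.07,
    "HexNAc4Hex5NeuAcNeuGc": 0.05,
    "HexNAc4Hex5": 0.08,
    "HexNAc4Hex3": 0.06,
    "HexNAc4Hex5Fuc": 0.08,
    "HexNAc2Hex6Phospho": 0.04,
    "HexNAc5Hex6NeuGc": 0.06,
}


@dataclass(frozen=True)
class SimConfig:
    n_proteins: int = 30
    n_glycopeptide_sequences: int = 40
    n_glycopeptides: int = 200  # glycopeptide spectra
    glycan_frequency: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_GLYCAN_FREQUENCY.items()
    )
    adduct_fractions: tuple[tuple[str, float], ...] = (("NH4", 0.21), ("Fe[III]", 0.07))
    charge_distribution: tuple[tuple[int, float], ...] = ((2, 0.45), (3, 0.40), (4, 0.15))
    isotope_offset_fractions: tuple[tuple[int, float], ...] = ((0, 1.0),)
    fragment_efficiency: float = 0.9
    noise_peaks: int = 20
    oxonium_contamination: float = 0.98
    rearrangement_rate: float = 0.23
    rearrangement_intensity_fraction: float = 0.04  # of the Y1 intensity
    mass_jitter_ppm: float = 1.5
    non_glyco_fraction: float = 0.25
    junk_fraction: float = 0.0
    junk_classes: tuple[str, ...] = ("none", "NH4", "Fe[III]", "Al[III]")
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("fragment_efficiency", self.fragment_efficiency),
            ("oxonium_contamination", self.oxonium_contamination),
            ("rearrangement_rate", self.rearrangement_rate),
            ("non_glyco_fraction", self.non_glyco_fraction),
            ("junk_fraction", self.junk_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if sum(f for _, f in self.adduct_fractions) > 1.0 + 1e-9:
            raise ValueError("adduct fractions exceed 1")


@dataclass
class SimulatedDataset:
    spectra: list[Spectrum]
    proteins: list[ProteinEntry]
    truth: pd.DataFrame


# amino-acid alphabets: glyco blocks carry exactly one sequon; non-glyco
# blocks contain no Asn so no sequon can arise
_CORE_AA = list("ADEFGHILQVW")
_NONGLYCO_AA = list("ADEFGHILQSTVW")


def _random_block(rng: np.random.Generator, with_sequon: bool) -> str:
    if with_sequon:
        n = int(rng.integers(7, 13))
        body = "".join(rng.choice(_CORE_AA, size=n))
        pos = int(rng.integers(0, n - 2))
        sequon = "N" + str(rng.choice(_CORE_AA)) + str(rng.choice(["S", "T"]))
        pep = body[:pos] + sequon + body[pos + 3:]
    else:
        n = int(rng.integers(6, 14))
        pep = "".join(rng.choice(_NONGLYCO_AA, size=n))
    return pep + str(rng.choice(["K", "R"]))


def _draw(rng: np.random.Generator, table: Sequence[tuple], ) -> object:
    keys = [k for k, _ in table]
    probs = np.array([p for _, p in table], dtype=float)
    if probs.sum() < 1.0 - 1e-9:  # implicit remainder class
        keys = keys + [None]
        probs = np.append(probs, 1.0 - probs.sum())
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _lognormal(rng: np.random.Generator, median: float, sigma: float = 0.7) -> float:
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _jitter(rng: np.random.Generator, mz: float, ppm: float) -> float:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm * 0.5) * 1e-6)


def _backbone_fragments(peptide: str, glycosite: int | None) -> list[float]:
    """Neutral b/y fragment masses, +HexNAc on glycosite-spanning ones."""
    aa = [peptide_mass(a) - WATER for a in peptide]
    prefix = np.cumsum(aa)
    total = prefix[-1] + WATER
    out = []
    for i in range(1, len(peptide)):
        b = prefix[i - 1]
        y = total - b
        if glycosite is not None:
            if glycosite < i:
                b += HEXNAC
            else:
                y += HEXNAC
        out.extend((b, y))
    return out


def _glycan_b_ions(g: GlycanComposition) -> list[float]:
    """1+ B/oxonium ions the glycan plausibly yields in stepped HCD."""
    out = []
    hexn, hexo, fuc = g["HexNAc"], g["Hex"], g["Fuc"]
    if hexn:
        out.append(oxonium_mz(_C("HexNAc")))
    if hexo:
        out.append(oxonium_mz(_C("Hex")))
    if hexn >= 2:
        out.append(oxonium_mz(_C("HexNAc2")))
    for j in range(1, min(5, hexo) + 1):
        out.append(oxonium_mz(GlycanComposition.from_dict({"HexNAc": 1, "Hex": j})))
    for t in ("NeuAc", "NeuGc", "NeuAcAc", "NeuGcAc"):
        if g[t]:
            c = GlycanComposition.from_dict({t: 1})
            out.append(oxonium_mz(c))
            out.append(oxonium_mz(c, water_losses=1))
            if hexn and hexo:
                out.append(
                    oxonium_mz(GlycanComposition.from_dict({"HexNAc": 1, "Hex": 1, t: 1}))
                )
    if fuc and hexn and hexo:
        out.append(oxonium_mz(_C("HexNAcHexFuc")))
    if g["Phospho"] and hexo:
        out.append(oxonium_mz(_C("HexPhospho")))
    return out


def _glycan_y_subs(g: GlycanComposition) -> list[GlycanComposition]:
    """Y-ion retained sub-glycans: core ladder plus the full composition."""
    subs: list[GlycanComposition] = [GlycanComposition()]
    hexn, hexo = g["HexNAc"], g["Hex"]
    for k in (1, 2):
        if hexn >= k:
            subs.append(GlycanComposition.from_dict({"HexNAc": k}))
    if hexn >= 2:
        for j in range(1, hexo + 1):
            subs.append(GlycanComposition.from_dict({"HexNAc": 2, "Hex": j}))
    if g not in subs:
        subs.append(g)
    return subs


#: background oxonium bundle injected into spectra regardless of identity
#: (co-isolation ghost peaks): HexNAc 204 plus sialic ions of both types.
_BACKGROUND_IONS = (
    oxonium_mz(_C("HexNAc")),
    oxonium_mz(_C("NeuAc")),
    oxonium_mz(_C("NeuAc"), 1),
    oxonium_mz(_C("NeuGc")),
    oxonium_mz(_C("NeuGc"), 1),
)


def simulate_spectrum(
    peptide: str,
    glycan: GlycanComposition,
    adduct=NO_ADDUCT,
    z: int = 2,
    cfg: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
    scan_id: str = "1",
    source_file: str = "sim.mgf",
    rt_min: float = 60.0,
    isotope_offset: int = 0,
) -> tuple[Spectrum, dict]:
    """One stepped-HCD-like glycopeptide spectrum plus its truth record.

    The glycosylated Asn is the peptide's first sequon. Metal adducts
    (``retained_on_y_ions``) shift every glycan-bearing Y ion and the
    precursor; ammonium shifts the precursor only, so its Y1 matches the
    fully protonated case.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    motifs = find_nglyco_motifs(peptide)
    if glycan and not motifs:
        raise ValueError(f"peptide {peptide} has no N-glycosylation sequon")
    glycosite = motifs[0] if glycan else None
    pep_mass = peptide_mass(peptide)
    neutral = pep_mass + glycan.mass + adduct.neutral_mass_shift

    mzs: list[float] = []
    ints: list[float] = []

    def add(mz: float, intensity: float, always: bool = False) -> None:
        if always or rng.random() < cfg.fragment_efficiency:
            mzs.append(_jitter(rng, mz, cfg.mass_jitter_ppm))
            ints.append(intensity)

    for frag in _backbone_fragments(peptide, glycosite):
        for c in range(1, max(1, z - 1) + 1):
            add(mz_from_neutral(frag, c), _lognormal(rng, 300.0))

    y1_intensity = 0.0
    y_shift = adduct.neutral_mass_shift if adduct.retained_on_y_ions else 0.0
    if glycan:
        for sub in _glycan_y_subs(glycan):
            shift = y_shift if sub else 0.0  # Y0 carries no glycan, no adduct
            intensity = _lognormal(rng, 900.0 if len(sub) <= 2 else 500.0)
            if sub.as_dict() == {"HexNAc": 1}:
                y1_intensity = intensity
            for c in range(1, z + 1):
                add(mz_from_neutral(pep_mass + sub.mass + shift, c), intensity)
        for bmz in _glycan_b_ions(glycan):
            add(bmz, _lognormal(rng, 600.0))
        if y1_intensity and rng.random() < cfg.rearrangement_rate:
            rearr = pep_mass + HEXNAC + MONOSACCHARIDES["Hex"].residue_mass
            frac = rng.uniform(0.2, 1.0) * cfg.rearrangement_intensity_fraction
            add(mz_from_neutral(rearr, 1), frac * y1_intensity, always=True)

    if rng.random() < cfg.oxonium_contamination:
        base = max(ints, default=1000.0)
        for bmz in _BACKGROUND_IONS:
            add(bmz, rng.uniform(0.01, 0.05) * base, always=True)

    top = mz_from_neutral(neutral, 1)
    for _ in range(cfg.noise_peaks):
        add(rng.uniform(150.0, min(top, 2500.0)), _lognormal(rng, 40.0), always=True)

    prec_mz = _jitter(
        rng, mz_from_neutral(neutral + isotope_offset * ISOTOPE_SPACING, z),
        cfg.mass_jitter_ppm,
    )
    spectrum = Spectrum(
        source_file=source_file,
        scan_id=scan_id,
        precursor_mz=prec_mz,
        precursor_charge=z,
        retention_time=rt_min,
        mz=np.array(mzs),
        intensity=np.array(ints),
    )
    truth = {
        "file": source_file,
        "scan": scan_id,
        "kind": "glyco" if glycan else "nonglyco",
        "peptide": peptide,
        "glycan": str(glycan),
        "adduct": adduct.name,
        "charge": z,
        "isotope_offset": isotope_offset,
        "rt_min": round(rt_min, 3),
        "glycosite": -1 if glycosite is None else glycosite,
    }
    return spectrum, truth


def make_dataset(cfg: SimConfig = SimConfig(), outdir=None) -> SimulatedDataset:
    """Generate proteins, spectra and the truth table; optionally write
    ``sim.mgf``, ``proteins.fasta`` and ``truth.tsv`` to ``outdir``.

    Byte-identical output for a fixed config. Includes a configurable
    fraction of non-glycopeptide spectra (subject to the same background
    oxonium contamination) and, when ``junk_fraction`` > 0, chimera-like
    spectra that match a random (glycan, adduct class) drawn uniformly
    over ``junk_classes`` — the random-match population the decoy-adduct
    FDR estimator is built to count.
    """
    rng = np.random.default_rng(cfg.seed)
    glyco_peptides: list[str] = []
    plain_peptides: list[str] = []
    proteins: list[ProteinEntry] = []
    seen: set[str] = set()
    for i in range(cfg.n_proteins):
        blocks = []
        for _ in range(int(rng.integers(4, 9))):
            want_sequon = len(glyco_peptides) < cfg.n_glycopeptide_sequences and (
                rng.random() < 0.5
            )
            for _attempt in range(20):
                block = _random_block(rng, want_sequon)
                if block not in seen:
                    break
            seen.add(block)
            blocks.append(block)
            (glyco_peptides if want_sequon else plain_peptides).append(block)
        proteins.append(
            ProteinEntry(f"SIM{i:04d}", f"synthetic protein {i}", "".join(blocks))
        )
    if not glyco_peptides:
        raise ValueError("no glycopeptide sequences generated; increase n_proteins")

    glycan_table = [(k, f) for k, f in cfg.glycan_frequency]
    rt_base = {p: float(rng.uniform(15.0, 170.0)) for p in glyco_peptides}

    n_glyco = cfg.n_glycopeptides
    n_total = int(round(n_glyco / max(1e-9, 1.0 - cfg.non_glyco_fraction - cfg.junk_fraction)))
    n_junk = int(round(n_total * cfg.junk_fraction))
    n_plain = n_total - n_glyco - n_junk

    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    scan = 0

    def next_scan() -> str:
        nonlocal scan
        scan += 1
        return str(scan)

    seen_protonated: set[str] = set()
    for _ in range(n_glyco):
        pep = str(rng.choice(glyco_peptides))
        gname = _draw(rng, glycan_table)
        adduct_name = _draw(rng, cfg.adduct_fractions)
        adduct = NO_ADDUCT if adduct_name is None else get_adduct(str(adduct_name))
        zdraw = _draw(rng, cfg.charge_distribution)
        z = 2 if zdraw is None else int(zdraw)
        off = _draw(rng, cfg.isotope_offset_fractions)
        off = 0 if off is None else int(off)
        if pep not in seen_protonated:
            # adducts are low-intensity satellites of the protonated form:
            # the first observation of a glycopeptide sequence is always
            # fully protonated at the correct monoisotopic peak
            adduct, off = NO_ADDUCT, 0
            seen_protonated.add(pep)
        s, t = simulate_spectrum(
            pep, _C(str(gname)), adduct, z, cfg, rng,
            scan_id=next_scan(),
            rt_min=rt_base[pep] + float(rng.uniform(-1.5, 1.5)),
            isotope_offset=off,
        )
        spectra.append(s)
        truth_rows.append(t)

    for _ in range(n_plain):
        pool = plain_peptides or glyco_peptides
        pep = str(rng.choice(pool))
        zdraw = _draw(rng, cfg.charge_distribution)
        z = 2 if zdraw is None else int(zdraw)
        s, t = simulate_spectrum(
            pep, GlycanComposition(), NO_ADDUCT, z, cfg, rng,
            scan_id=next_scan(), rt_min=float(rng.uniform(10.0, 175.0)),
        )
        spectra.append(s)
        truth_rows.append(t)

    for _ in range(n_junk):
        pep = str(rng.choice(glyco_peptides))
        gname = _draw(rng, glycan_table)
        cls = str(rng.choice(list(cfg.junk_classes)))
        adduct = NO_ADDUCT if cls == "none" else get_adduct(cls)
        zdraw = _draw(rng, cfg.charge_distribution)
        z = 2 if zdraw is None else int(zdraw)
        s, t = simulate_spectrum(
            pep, _C(str(gname)), adduct, z, cfg, rng,
            scan_id=next_scan(), rt_min=float(rng.uniform(10.0, 175.0)),
        )
        t["kind"] = "junk"
        spectra.append(s)
        truth_rows.append(t)

    truth = pd.DataFrame(truth_rows)
    ds = SimulatedDataset(spectra, proteins, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mgf(spectra, outdir / "sim.mgf")
        write_fasta(proteins, outdir / "proteins.fasta")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return ds
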