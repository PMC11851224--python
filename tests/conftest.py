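"""Shared fixtures: synthetic datasets, pipeline runs and oracles.

The heavyweight simulation studies (noiseless closure, adduct-FDR
calibration, the ammonium-isobar stress test) are session-scoped so the
per-module tests and the acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from nglycofind import (
    FilterSpec,
    GlycanComposition,
    SearchParams,
    YSearchParams,
    build_seed_list,
    default_glycan_set,
    filter_spectra,
    get_adduct,
    read_fasta,
    search,
    threshold_fdr,
)
from nglycofind.chem import NO_ADDUCT, find_nglyco_motifs, neutral_from_mz
from nglycofind.finder import SeedPeptide, assign_best, enumerate_candidates, expand_glycoforms
from nglycofind.msio import write_fasta
from nglycofind.scoring import GlycoScoreConfig
from nglycofind.search import PeptideCandidate
from nglycofind.simulate import DEFAULT_GLYCAN_FREQUENCY, SimConfig, make_dataset, simulate_spectrum

#: generator settings for noiseless fixtures: every theoretical peak
#: present, no noise, no background, no mass error
NOISELESS = dict(
    fragment_efficiency=1.0,
    noise_peaks=0,
    oxonium_contamination=0.0,
    rearrangement_rate=0.0,
    mass_jitter_ppm=0.0,
)


def run_pipeline(ds, glycans, seed=7, yparams=None):
    """filter -> decoy database -> search -> FDR -> seeds -> expand."""
    index = filter_spectra(ds.spectra, FilterSpec())
    import tempfile, os

    d = tempfile.mkdtemp()
    write_fasta(ds.proteins, os.path.join(d, "db.fasta"))
    proteins = read_fasta(os.path.join(d, "db.fasta"), "randomized", seed)
    params = SearchParams(glycan_set=tuple(glycans))
    matches = search(ds.spectra, proteins, params, subset_index=index)
    accepted = threshold_fdr(matches, params, allow_no_decoys=True)
    seeds = build_seed_list([m for m in accepted if not m.is_decoy])
    out = expand_glycoforms(
        ds.spectra, seeds, params.glycans(), yparams or YSearchParams(),
        subset_index=index,
    )
    return out


@pytest.fixture(scope="session")
def closure_run():
    """Noiseless 200-glycopeptide dataset pushed through the full pipeline."""
    cfg = SimConfig(
        seed=2, n_glycopeptides=200, non_glyco_fraction=0.2,
        adduct_fractions=(("NH4", 0.2), ("Fe[III]", 0.1)),
        **NOISELESS,
    )
    ds = make_dataset(cfg)
    out = run_pipeline(ds, default_glycan_set())
    return ds, out


@pytest.fixture(scope="session")
def calibration_run():
    """2000-spectrum run with junk chimeras and the aluminum decoy adduct."""
    cfg = SimConfig(
        seed=11, n_glycopeptides=1200, non_glyco_fraction=0.15,
        junk_fraction=0.25, fragment_efficiency=0.95, noise_peaks=10,
        oxonium_contamination=0.9, mass_jitter_ppm=1.0,
        adduct_fractions=(("NH4", 0.2), ("Fe[III]", 0.07)),
    )
    ds = make_dataset(cfg)
    glycans = [GlycanComposition.parse(k) for k in DEFAULT_GLYCAN_FREQUENCY]
    out = run_pipeline(ds, glycans)
    from nglycofind import estimate_adduct_fdr

    per_class, overall, kept = estimate_adduct_fdr(out, get_adduct("Al[III]"))
    truth = ds.truth.set_index(["file", "scan"])
    n_false = sum(1 for m in kept if truth.loc[m.spectrum].kind == "junk")
    return {
        "per_class": per_class,
        "overall_estimate": overall,
        "realized_rate": n_false / len(kept),
        "n_kept": len(kept),
        "kept": kept,
        "truth": ds.truth,
    }


def _stress_assign(adducts, sialic_penalty, n=40, seed=5):
    """Assign n NH4-adducted HexNAc2Hex9 spectra under a given adduct policy."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, **{**NOISELESS, "mass_jitter_ppm": 0.5})
    g = GlycanComposition.parse("HexNAc2Hex9")
    nh4 = get_adduct("NH4")
    peptides = ["AVDLNGTEWSK", "LLNVTHDFSR", "EFNKTLIEDRK", "GVVNSTHQEWAK", "IDFLNSSVVQK"]
    glycans = tuple(default_glycan_set())
    yp = YSearchParams(
        adducts=adducts,
        score_config=GlycoScoreConfig(sialic_missing_penalty=sialic_penalty),
    )
    tally = {"correct": 0, "isobar_drift": 0, "dropped": 0, "other": 0}
    for i in range(n):
        pep = peptides[i % len(peptides)]
        seed_pep = SeedPeptide(
            PeptideCandidate(pep, (), ("P1",), tuple(find_nglyco_motifs(pep)))
        )
        s, _ = simulate_spectrum(pep, g, nh4, 3, cfg, rng, scan_id=str(i))
        cands = enumerate_candidates(
            neutral_from_mz(s.precursor_mz, 3), seed_pep, glycans, yp
        )
        m = assign_best(s, seed_pep, cands, yp)
        if m is None:
            tally["dropped"] += 1
        elif (
            str(m.glycan) == "HexNAc2Hex9"
            and m.adduct.name == "NH4"
            and m.isotope_offset == 0
        ):
            tally["correct"] += 1
        elif str(m.glycan) == "HexNAc4Hex3NeuAc2" and m.isotope_offset == 1:
            tally["isobar_drift"] += 1
        else:
            tally["other"] += 1
    tally["n"] = n
    return tally


@pytest.fixture(scope="session")
def nh4_stress_run():
    full = (NO_ADDUCT, get_adduct("NH4"), get_adduct("Fe[III]"), get_adduct("Al[III]"))
    return {
        "no_adducts_no_penalty": _stress_assign((NO_ADDUCT,), 0.0),
        "no_adducts_default": _stress_assign((NO_ADDUCT,), -5.0),
        "with_nh4": _stress_assign(full, -5.0),
    }


@pytest.fixture(scope="session")
def enumeration_oracle():
    """Brute-force (glycan, adduct, offset) enumeration, plain arithmetic."""

    def oracle(precursor_neutral, seed_mass, glycans, params: YSearchParams):
        out = set()
        tol = precursor_neutral * params.precursor_tol_ppm * 1e-6
        for g in glycans:
            for a in params.adducts:
                for off in params.isotope_offsets:
                    err = (
                        precursor_neutral
                        - off * params.isotope_spacing
                        - (seed_mass + g.mass + a.neutral_mass_shift)
                    )
                    if abs(err) <= tol:
                        out.add((str(g), a.name, off))
        return out

    return oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
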