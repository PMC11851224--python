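"""Glycan B/Y scoring: expected fragments, penalties, background statistics."""

import numpy as np
import pytest

from nglycofind.chem import (
    GlycanComposition,
    NO_ADDUCT,
    find_nglyco_motifs,
    get_adduct,
    oxonium_mz,
    peptide_mass,
)
from nglycofind.scoring import (
    GlycoScoreConfig,
    background_ion_stats,
    expected_fragments,
    glyco_score,
)
from nglycofind.search import GlycopeptideMatch, PeptideCandidate
from nglycofind.simulate import SimConfig, simulate_spectrum
from .test_msio import make_spectrum
from .test_search import NOISELESS, noiseless_spectrum

G = GlycanComposition.parse
PEP = "AVDLNGTEWSK"
PEP_MASS = peptide_mass(PEP)


def frag_labels(frags, series):
    return {f.label for f in frags if f.series == series}


class TestExpectedFragments:
    def test_oligomannose_ladder(self):
        frags = expected_fragments(PEP_MASS, G("HexNAc2Hex9"), z=2)
        y = frag_labels(frags, "Y")
        assert "Y:HexNAc" in y and "Y:HexNAc2" in y
        for j in range(1, 10):
            assert f"Y:HexNAc2Hex{j}".replace("Hex1", "Hex") in y
        b = frag_labels(frags, "B")
        for j in range(1, 4):  # B sub-compositions capped at 4 residues
            assert f"B:HexNAcHex{j}".replace("Hex1", "Hex") in b

    def test_empty_glycan_y0_only(self):
        frags = expected_fragments(PEP_MASS, GlycanComposition(), z=2)
        assert frag_labels(frags, "B") == set()
        assert frag_labels(frags, "Y") == {"Y0"}

    def test_sialylated_b_ions_match_subcomposition_oracle(self):
        """Every B ion of HexNAc4Hex5NeuGc2 is a true sub-composition of
        size <= 4 (brute-force audit); NeuGc diagnostics present at their
        printed masses, and no NeuAc ion is expected."""
        g = G("HexNAc4Hex5NeuGc2")
        frags = [f for f in expected_fragments(PEP_MASS, g, z=2) if f.series == "B"]
        mzs = {round(f.mz, 3) for f in frags}
        assert 290.087 in mzs and 308.098 in mzs  # NeuGc -H2O / intact
        assert "B:HexNAcHexNeuGc" in {f.label for f in frags}
        for f in frags:
            assert g.contains(f.sub_composition)
            assert 1 <= len(f.sub_composition) <= 4
            assert f.sub_composition["NeuAc"] == 0

    def test_metal_adduct_doubles_y_ions(self):
        plain = frag_labels(expected_fragments(PEP_MASS, G("HexNAc2Hex5"), z=2), "Y")
        fe = frag_labels(
            expected_fragments(PEP_MASS, G("HexNAc2Hex5"), get_adduct("Fe[III]"), 2),
            "Y",
        )
        assert plain < fe
        assert any(label.endswith("+Fe[III]") for label in fe)

    def test_hexnac_free_composition_rejected(self):
        with pytest.raises(ValueError, match="HexNAc"):
            expected_fragments(PEP_MASS, G("Hex5"))


def score_of(spectrum, glycan, cfg=GlycoScoreConfig(), adduct=NO_ADDUCT):
    s, _ = glyco_score(spectrum, PEP_MASS, G(glycan), adduct, cfg, 2)
    return s


class TestGlycoScore:
    def test_matched_sialylated_assignment_not_penalized(self):
        s = noiseless_spectrum(PEP, "HexNAc4Hex5NeuGc2")
        score, ledger = glyco_score(s, PEP_MASS, G("HexNAc4Hex5NeuGc2"), z=2)
        assert score > 0
        assert "missing-NeuGc-ions" not in ledger.penalties

    def test_missing_sialic_ions_heavily_penalized(self):
        s = noiseless_spectrum(PEP, "HexNAc4Hex5")  # no sialic ions anywhere
        cfg = GlycoScoreConfig()
        with_pen, ledger = glyco_score(s, PEP_MASS, G("HexNAc4Hex5NeuAc2"), z=2)
        no_pen, _ = glyco_score(
            s, PEP_MASS, G("HexNAc4Hex5NeuAc2"),
            cfg=GlycoScoreConfig(sialic_missing_penalty=0.0), z=2,
        )
        assert with_pen == no_pen + cfg.sialic_missing_penalty
        assert ledger.penalties["missing-NeuAc-ions"] == cfg.sialic_missing_penalty

    def test_fucose_unsupported_small_penalty(self):
        s = noiseless_spectrum(PEP, "HexNAc4Hex5")
        cfg = GlycoScoreConfig()
        with_pen, ledger = glyco_score(s, PEP_MASS, G("HexNAc4Hex5Fuc"), z=2)
        no_pen, _ = glyco_score(
            s, PEP_MASS, G("HexNAc4Hex5Fuc"),
            cfg=GlycoScoreConfig(fucose_unsupported_penalty=0.0), z=2,
        )
        assert with_pen == no_pen + cfg.fucose_unsupported_penalty

    def test_sialic_background_asymmetry_is_literal(self):
        """NeuGc oxonium background changes the score of a NeuGc-free
        candidate by exactly zero."""
        base = noiseless_spectrum(PEP, "HexNAc2Hex5")
        with_bg = make_spectrum(
            np.concatenate([base.mz, [oxonium_mz(G("NeuGc")), oxonium_mz(G("NeuGc"), 1)]]),
            np.concatenate([base.intensity, [50.0, 50.0]]),
            precursor_mz=base.precursor_mz, precursor_charge=2,
        )
        assert score_of(with_bg, "HexNAc2Hex5") == score_of(base, "HexNAc2Hex5")

    def test_supporting_ion_monotonicity(self):
        base = noiseless_spectrum(PEP, "HexNAc2Hex5")
        richer = make_spectrum(
            np.concatenate([base.mz, [oxonium_mz(G("Hex2"))]]),
            np.concatenate([base.intensity, [99.0]]),
            precursor_mz=base.precursor_mz, precursor_charge=2,
        )
        assert score_of(richer, "HexNAc2Hex5") >= score_of(base, "HexNAc2Hex5")

    def test_contradicting_ion_monotonicity(self):
        base = noiseless_spectrum(PEP, "HexNAc2Hex5")
        hexp = oxonium_mz(G("HexPhospho"))  # phospho ion, candidate has none
        contradicted = make_spectrum(
            np.concatenate([base.mz, [hexp]]),
            np.concatenate([base.intensity, [99.0]]),
            precursor_mz=base.precursor_mz, precursor_charge=2,
        )
        assert score_of(contradicted, "HexNAc2Hex5") == (
            score_of(base, "HexNAc2Hex5") + GlycoScoreConfig().point_per_contradicting_ion
        )

    def test_true_glycan_beats_mass_matched_alternatives(self):
        """On noiseless spectra the generating glycan outscores same-mass
        (within 5 ppm, over offsets/adducts) alternatives in >= 90% of
        cases."""
        from nglycofind.finder import SeedPeptide, YSearchParams, enumerate_candidates
        from nglycofind.chem import neutral_from_mz
        from nglycofind.glycansets import default_glycan_set

        glycans = tuple(default_glycan_set())
        yp = YSearchParams()
        seed_pep = SeedPeptide(
            PeptideCandidate(PEP, (), ("P",), tuple(find_nglyco_motifs(PEP)))
        )
        rng = np.random.default_rng(3)
        cfg = SimConfig(seed=3, **NOISELESS)
        trues = ["HexNAc2Hex9", "HexNAc4Hex5NeuGc2", "HexNAc4Hex5Fuc",
                 "HexNAc4Hex5NeuAc2", "HexNAc2Hex6Phospho", "HexNAc5Hex6NeuGc"]
        wins = total = 0
        for i in range(30):
            gname = trues[i % len(trues)]
            s, _ = simulate_spectrum(PEP, G(gname), NO_ADDUCT, 2, cfg, rng, scan_id=str(i))
            cands = enumerate_candidates(
                neutral_from_mz(s.precursor_mz, 2), seed_pep, glycans, yp
            )
            alternatives = [c for c in cands if str(c.glycan) != gname]
            if not alternatives:
                continue
            true_score, _ = glyco_score(s, PEP_MASS, G(gname), z=2)
            total += 1
            if all(
                glyco_score(s, PEP_MASS, c.glycan, c.adduct, z=2)[0] < true_score
                for c in alternatives
            ):
                wins += 1
        assert total >= 10
        assert wins / total >= 0.9


class TestBackgroundStats:
    def _matches_and_spectra(self, p, n, glycan="HexNAc2Hex5", seed=21):
        cfg = SimConfig(
            seed=seed, oxonium_contamination=p, fragment_efficiency=1.0,
            noise_peaks=0, rearrangement_rate=0.0, mass_jitter_ppm=0.0,
        )
        rng = np.random.default_rng(seed)
        cand = PeptideCandidate(PEP, (), ("P",), tuple(find_nglyco_motifs(PEP)))
        spectra, matches = [], []
        for i in range(n):
            s, _ = simulate_spectrum(PEP, G(glycan), NO_ADDUCT, 2, cfg, rng, scan_id=str(i))
            spectra.append(s)
            matches.append(
                GlycopeptideMatch(spectrum=s.key, peptide=cand, glycan=G(glycan))
            )
        return matches, spectra

    def test_unexpected_fraction_tracks_contamination(self):
        p, n = 0.30, 300
        matches, spectra = self._matches_and_spectra(p, n)
        table = background_ion_stats(matches, spectra).set_index("ion")
        frac = table.loc["NeuGc-H2O", "observed_not_expected"] / n
        sigma = (p * (1 - p) / n) ** 0.5
        assert abs(frac - p) < 4 * sigma

    def test_expected_ions_never_unexpected(self):
        matches, spectra = self._matches_and_spectra(0.0, 20)
        table = background_ion_stats(matches, spectra).set_index("ion")
        assert table.loc["HexNAc", "observed"] == 20
        assert table.loc["HexNAc", "observed_not_expected"] == 0

    def test_no_matches_empty_counts(self):
        table = background_ion_stats([], [])
        assert (table["observed"] == 0).all()

    def test_rearrangement_flagging(self):
        cfg = SimConfig(
            seed=8, oxonium_contamination=0.0, fragment_efficiency=1.0,
            noise_peaks=0, rearrangement_rate=1.0,
            rearrangement_intensity_fraction=0.5, mass_jitter_ppm=0.0,
        )
        rng = np.random.default_rng(8)
        cand = PeptideCandidate(PEP, (), ("P",), tuple(find_nglyco_motifs(PEP)))
        spectra, matches = [], []
        for i in range(10):
            s, _ = simulate_spectrum(PEP, G("HexNAc2Hex9"), NO_ADDUCT, 2, cfg, rng, scan_id=str(i))
            spectra.append(s)
            matches.append(
                GlycopeptideMatch(spectrum=s.key, peptide=cand, glycan=G("HexNAc2Hex9"))
            )
        table = background_ion_stats(matches, spectra).set_index("ion")
        assert table.loc["Y+HexNAcHex", "observed"] == 10
        # half-of-Y1 rearrangement peaks are far above the 5% heuristic
        flagged = sum("rearrangement" in m.flags for m in matches)
        assert flagged >= 8
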