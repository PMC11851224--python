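"""In-silico digestion, peptide scoring, the database search and FDR."""

import numpy as np
import pytest

from nglycofind.chem import (
    GlycanComposition,
    MONOSACCHARIDES,
    NO_ADDUCT,
    find_nglyco_motifs,
    mz_from_neutral,
)
from nglycofind.glycansets import default_glycan_set
from nglycofind.msio import ProteinEntry
from nglycofind.search import (
    GlycopeptideMatch,
    PeptideCandidate,
    SearchParams,
    build_peptide_index,
    digest,
    score_peptide,
    search,
    strip_oxonium_peaks,
    threshold_fdr,
)
from nglycofind.simulate import SimConfig, simulate_spectrum
from .test_msio import make_spectrum

HEXNAC = MONOSACCHARIDES["HexNAc"].residue_mass

BARE = SearchParams(
    oxidation_m=False, pyroglu_nterm_q=False, protein_nterm_variants=False,
    min_peptide_length=1,
)


def brute_force_tryptic(seq: str, max_mc: int, lo: int, hi: int) -> set[str]:
    """Independent enumeration of fully tryptic peptides over all substrings."""
    def cleavable(i):  # bond after residue i-1
        return 0 < i < len(seq) and seq[i - 1] in "KR" and seq[i] != "P"

    out = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if not (i == 0 or cleavable(i)):
                continue
            if not (j == len(seq) or cleavable(j)):
                continue
            internal = sum(1 for k in range(i + 1, j) if cleavable(k))
            if internal <= max_mc and lo <= j - i <= hi:
                out.add(seq[i:j])
    return out


class TestDigest:
    @pytest.mark.parametrize("seq", ["MAKRGK", "KKPRK", "AAKPGGRLLK"])
    @pytest.mark.parametrize("mc", [0, 1, 3])
    def test_matches_brute_force(self, seq, mc):
        prot = ProteinEntry("P", "", seq)
        params = SearchParams(
            max_missed_cleavages=mc, oxidation_m=False, pyroglu_nterm_q=False,
            protein_nterm_variants=False, min_peptide_length=1,
        )
        got = {c.sequence for c in digest(prot, params)}
        assert got == brute_force_tryptic(seq, mc, 1, 60)

    def test_no_cleavage_site_whole_protein(self):
        prot = ProteinEntry("P", "", "AVDLNGTEWS")
        cands = digest(prot, BARE)
        assert [c.sequence for c in cands] == ["AVDLNGTEWS"]

    def test_missed_cleavage_monotonicity(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        prot = ProteinEntry("P", "", seq)
        prev: set = set()
        for mc in range(4):
            params = SearchParams(
                max_missed_cleavages=mc, oxidation_m=False, pyroglu_nterm_q=False,
                protein_nterm_variants=False, min_peptide_length=1,
            )
            cur = {c.sequence for c in digest(prot, params)}
            assert prev <= cur
            prev = cur

    def test_nterm_variants(self):
        prot = ProteinEntry("P", "", "MAVDLNGTEWSKGGR")
        cands = digest(prot, SearchParams(min_peptide_length=3))
        seqs_mods = {(c.sequence, c.mods_string()) for c in cands}
        assert ("MAVDLNGTEWSK", "") in seqs_mods
        assert ("AVDLNGTEWSK", "") in seqs_mods  # Met removed
        assert ("MAVDLNGTEWSK", "Acetyl@-1") in seqs_mods
        assert ("AVDLNGTEWSK", "Acetyl@-1") in seqs_mods

    def test_oxidation_and_pyroglu(self):
        prot = ProteinEntry("P", "", "GGKQMNMTAK")
        cands = digest(prot, SearchParams(min_peptide_length=3))
        mods = {c.mods_string() for c in cands if c.sequence == "QMNMTAK"}
        assert "" in mods
        assert "Gln->pyro-Glu@0" in mods
        assert "Oxidation@1" in mods and "Oxidation@3" in mods
        # cap of 2 variable mods: pyroGlu + both oxidations never together
        assert "Gln->pyro-Glu@0;Oxidation@1;Oxidation@3" not in mods

    def test_motif_positions_recorded(self):
        prot = ProteinEntry("P", "", "AVDLNGTEWSK")
        (cand,) = [c for c in digest(prot, BARE) if c.sequence == "AVDLNGTEWSK"]
        assert cand.motif_positions == (4,)

    def test_decoy_flag_inherited(self):
        prot = ProteinEntry("D", "", "AVDLNGTEWSK", is_decoy=True)
        assert all(c.is_decoy for c in digest(prot, BARE))


class TestStripOxonium:
    def test_strips_oxonium_keeps_rest(self):
        s = make_spectrum([204.0867, 500.0])
        out = strip_oxonium_peaks(s)
        assert list(out.mz) == [500.0]
        assert list(s.mz) == [204.0867, 500.0]  # input untouched

    def test_no_oxonium_unchanged(self):
        s = make_spectrum([450.0, 900.0])
        assert list(strip_oxonium_peaks(s).mz) == [450.0, 900.0]

    def test_idempotent(self):
        s = make_spectrum([138.0550, 204.0867, 366.1395, 731.5])
        once = strip_oxonium_peaks(s)
        twice = strip_oxonium_peaks(once)
        assert list(once.mz) == list(twice.mz) == [731.5]


NOISELESS = dict(
    fragment_efficiency=1.0, noise_peaks=0, oxonium_contamination=0.0,
    rearrangement_rate=0.0, mass_jitter_ppm=0.0,
)


def noiseless_spectrum(pep, glycan="", adduct=NO_ADDUCT, z=2, seed=0, **kw):
    cfg = SimConfig(seed=seed, **NOISELESS)
    rng = np.random.default_rng(seed)
    s, truth = simulate_spectrum(
        pep, GlycanComposition.parse(glycan), adduct, z, cfg, rng, **kw
    )
    return s


class TestScorePeptide:
    def test_full_backbone_reaches_theoretical_max(self):
        pep = "AVDLNGTEWSK"
        cand = PeptideCandidate(pep, (), ("P",), tuple(find_nglyco_motifs(pep)))
        s = noiseless_spectrum(pep)  # plain peptide: b/y only
        score, _ = score_peptide(s, cand, glycan_on_motif=False)
        assert score == 2 * (len(pep) - 1)

    def test_glycopeptide_gets_y1_bonus(self):
        pep = "AVDLNGTEWSK"
        cand = PeptideCandidate(pep, (), ("P",), tuple(find_nglyco_motifs(pep)))
        s = noiseless_spectrum(pep, "HexNAc2Hex9")
        score, _ = score_peptide(s, cand, glycan_on_motif=True)
        assert score == 2 * (len(pep) - 1) + 1

    def test_empty_spectrum_scores_zero(self):
        cand = PeptideCandidate("AVDLNGTEWSK", (), ("P",), (4,))
        score, inten = score_peptide(make_spectrum([]), cand)
        assert score == 0 and inten == 0

    def test_missing_hexnac_retention_lowers_score(self):
        """Shifting every glycosite-spanning y ion down by one HexNAc
        (no core retention) must strictly lower the score."""
        pep = "AVDLNGTEWSK"
        cand = PeptideCandidate(pep, (), ("P",), (4,))
        from nglycofind.search import _fragment_masses

        frags = _fragment_masses(cand, glycosite=4)
        good = make_spectrum([mz_from_neutral(m, 1) for _, m in frags])
        shifted = make_spectrum(
            [
                mz_from_neutral(m - (HEXNAC if name.startswith("y") and int(name[1:]) >= len(pep) - 4 else 0.0), 1)
                for name, m in frags
            ]
        )
        s_good, _ = score_peptide(good, cand)
        s_shift, _ = score_peptide(shifted, cand)
        assert s_shift < s_good


class TestSearch:
    def _db(self):
        return [
            ProteinEntry("P1", "", "MKAVDLNGTEWSKGGR"),
            ProteinEntry("P2", "", "MKLLDVTHDFSKAAR"),
        ]

    def test_recovers_fixture_glycopeptide(self):
        s = noiseless_spectrum("AVDLNGTEWSK", "HexNAc2Hex9", z=2)
        params = SearchParams(glycan_set=tuple(default_glycan_set()))
        (m,) = search([s], self._db(), params)
        assert m.peptide.sequence == "AVDLNGTEWSK"
        truth_mass = GlycanComposition.parse("HexNAc2Hex9").mass
        assert m.glycan.mass == pytest.approx(truth_mass, abs=0.02)
        assert abs(m.precursor_error_ppm) <= 5.0

    def test_unmatchable_precursor_gives_nothing(self):
        s = make_spectrum([204.0867, 500.0], precursor_mz=600.0, precursor_charge=2)
        params = SearchParams(glycan_set=tuple(default_glycan_set()))
        assert search([s], self._db(), params) == []

    def test_decoy_only_database_flags_decoy(self):
        s = noiseless_spectrum("AVDLNGTEWSK", "HexNAc2Hex9")
        db = [ProteinEntry("DECOY_P1", "", "MKAVDLNGTEWSKGGR", is_decoy=True)]
        params = SearchParams(glycan_set=tuple(default_glycan_set()))
        (m,) = search([s], db, params)
        assert m.is_decoy

    def test_empty_glycan_set_rejected(self):
        with pytest.raises(ValueError, match="glycan"):
            search([], self._db(), SearchParams(glycan_set=()))

    def test_precursor_candidate_equivalence(self, rng):
        """Index lookup equals a brute-force cross-product filter."""
        params = SearchParams(glycan_set=tuple(default_glycan_set()[:150]))
        index = build_peptide_index(self._db(), params)
        masses = np.array([c.neutral_mass for c in index])
        glycans = params.glycans()
        for _ in range(500):
            neutral = float(rng.uniform(2000.0, 5000.0))
            tol = neutral * params.precursor_tol_ppm * 1e-6
            brute = {
                (c.key, str(g))
                for c in index
                for g in glycans
                if abs(neutral - c.neutral_mass - g.mass) <= tol
            }
            fast = set()
            for g in glycans:
                target = neutral - g.mass
                lo = np.searchsorted(masses, target - tol, "left")
                hi = np.searchsorted(masses, target + tol, "right")
                fast |= {(index[k].key, str(g)) for k in range(lo, hi)}
            assert fast == brute


def fdr_matches(spec):
    """Build one match per (score, is_decoy) pair with unique peptides."""
    out = []
    for i, (score, is_decoy) in enumerate(spec):
        pep = PeptideCandidate(
            f"PEP{i:04d}K", (), (f"{'DECOY_' if is_decoy else ''}P{i}",),
            (0,), is_decoy,
        )
        out.append(
            GlycopeptideMatch(
                spectrum=("f", str(i)), peptide=pep,
                glycan=GlycanComposition.parse("HexNAc2Hex5"),
                peptide_score=float(score),
            )
        )
    return out


class TestThresholdFDR:
    def test_closed_form_one_percent(self):
        matches = fdr_matches([(10, False)] * 100 + [(10, True)])
        accepted = threshold_fdr(matches, SearchParams(fdr_threshold=0.01))
        assert len(accepted) == 101  # 1 decoy / 100 targets = 1%

    def test_matches_brute_force_over_cutpoints(self, rng):
        scores = list(rng.integers(1, 30, size=100))
        flags = [False] * 100
        for i in rng.choice(100, size=5, replace=False):
            flags[i] = True
        spec = list(zip(scores, flags))
        matches = fdr_matches(spec)
        accepted = threshold_fdr(matches, SearchParams(fdr_threshold=0.05))

        best_n, best_set = -1, set()
        for t in sorted({s for s, _ in spec}):
            tgt = sum(1 for s, d in spec if s >= t and not d)
            dec = sum(1 for s, d in spec if s >= t and d)
            if tgt and dec / tgt <= 0.05 and tgt > best_n:
                best_n = tgt
                best_set = {i for i, (s, d) in enumerate(spec) if s >= t}
        assert {m.spectrum[1] for m in accepted} == {str(i) for i in best_set}

    def test_fdr_zero_requires_above_best_decoy(self):
        matches = fdr_matches([(12, False), (11, False), (10, True), (10, False)])
        accepted = threshold_fdr(matches, SearchParams(fdr_threshold=1e-9))
        assert {m.peptide_score for m in accepted} == {12.0, 11.0}

    def test_no_decoys_is_an_error(self):
        matches = fdr_matches([(10, False)] * 5)
        with pytest.raises(ValueError, match="decoy"):
            threshold_fdr(matches)
        assert len(threshold_fdr(matches, allow_no_decoys=True)) == 5


class TestDefaultGlycanSet:
    def test_contains_reported_compositions(self):
        names = {str(g) for g in default_glycan_set()}
        for required in (
            "HexNAc2Hex9",
            "HexNAc4Hex5NeuGc2",
            "HexNAc4Hex5NeuAcNeuGc",
            "HexNAc4Hex3NeuAc2",
            "HexNAc2Hex8",
        ):
            assert required in names

    def test_sialic_antenna_constraint(self):
        for g in default_glycan_set():
            sialic = sum(g[t] for t in ("NeuAc", "NeuAcAc", "NeuGc", "NeuGcAc"))
            assert sialic <= max(0, g["HexNAc"] - 2)

    def test_size_and_determinism(self):
        a = default_glycan_set()
        assert 700 <= len(a) <= 1100
        assert len({str(g) for g in a}) == len(a)  # deduplicated
        assert [str(g) for g in a] == [str(g) for g in default_glycan_set()]
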