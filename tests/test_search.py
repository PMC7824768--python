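"""Target-decoy database construction, spectrum matching, and FDR control."""

import numpy as np
import pytest

from venomkit.annotate import Interval, PrecursorModel
from venomkit.digest import Peptidoform, ProteolyticPeptide, apply_modifications, digest
from venomkit.masses import Proteoform, mz
from venomkit.search import (FIXED_CAM, PSM, PeptidoformIndex, Spectrum,
                             build_search_db, match_spectrum,
                             score_match, sequence_coverage, target_decoy_fdr)
from venomkit.simulate import gen_msms_run, gen_noise_spectra


def _precursor(signal="M" + "L" * 19, pro="EEDR", mature="CAAKCAAC"):
    aa = signal + pro + mature
    k = len(signal)
    return PrecursorModel(
        aa, Interval(1, k),
        Interval(k + 1, k + len(pro)) if pro else None,
        Interval(k + len(pro) + 1, len(aa)), None, False)


class TestDatabase:
    def test_two_part_precursors_yield_double_targets(self):
        db = build_search_db([_precursor() for _ in range(217)])
        assert db.n_targets == 434
        assert db.n_decoys == 434

    def test_empty_propeptide_single_target(self):
        db = build_search_db([_precursor(pro="")])
        assert db.n_targets == 1
        assert db.n_decoys == 1

    def test_decoys_are_full_reversals(self):
        db = build_search_db([_precursor(mature="ACDECCCC")])
        targets = {e.accession: e for e in db.entries if not e.is_decoy}
        for acc, entry in targets.items():
            decoy = next(e for e in db.entries
                         if e.accession == "DECOY_" + acc)
            assert decoy.sequence == entry.sequence[::-1]
            assert decoy.is_decoy


def _spectrum_for(form: Peptidoform, sid="s1", charge=2, noise=0):
    from venomkit.digest import fragment_ions
    peaks = [(ion.mz, 1000.0) for ion in fragment_ions(form)]
    rng = np.random.default_rng(5)
    for _ in range(noise):
        peaks.append((float(rng.uniform(100, 1500)), 50.0))
    return Spectrum(sid, mz(form.neutral_mass(), charge), charge,
                    tuple(sorted(peaks)))


@pytest.fixture(scope="module")
def small_index():
    precursors = [
        _precursor(mature="CIQRHRSCRKSSECCGCSVCQCNLFGQNCQCKSGGLIAC"),
        _precursor(mature="CWWHHKCNNCLLTTRCPPQQCAAC"),
        _precursor(mature="CAFEGKCHIKDCLMNPRCQESTCC"),
    ]
    return PeptidoformIndex(build_search_db(precursors), "trypsin", 2,
                            fixed=FIXED_CAM)


class TestMatchSpectrum:
    def test_noise_free_spectrum_matches_true_peptide(self, small_index):
        """All 42 b/y ions of the 22-mer match when present."""
        parent = Proteoform("CIQRHRSCRKSSECCGCSVCQCNLFGQNCQCKSGGLIAC")
        pep = [p for p in digest(parent, "trypsin", 0)
               if p.sequence == "SSECCGCSVCQCNLFGQNCQCK"][0]
        form = apply_modifications(pep, FIXED_CAM, None, 0)[0]
        psms = match_spectrum(_spectrum_for(form), small_index)
        assert len(psms) == 1
        assert psms[0].peptidoform.sequence == "SSECCGCSVCQCNLFGQNCQCK"
        assert psms[0].n_matched_fragments == 42
        assert not psms[0].is_decoy

    def test_score_drops_without_true_peptide(self, small_index):
        parent = Proteoform("CIQRHRSCRKSSECCGCSVCQCNLFGQNCQCKSGGLIAC")
        pep = [p for p in digest(parent, "trypsin", 0)
               if p.sequence == "SSECCGCSVCQCNLFGQNCQCK"][0]
        form = apply_modifications(pep, FIXED_CAM, None, 0)[0]
        spectrum = _spectrum_for(form, noise=5)
        with_true = match_spectrum(spectrum, small_index)[0].score
        other_index = PeptidoformIndex(
            build_search_db([_precursor(mature="CWWHHKCNNCLLTTRCPPQQCAAC")]),
            "trypsin", 2, fixed=FIXED_CAM)
        without = match_spectrum(spectrum, other_index)
        assert not without or without[0].score < with_true

    def test_precursor_tolerance_gate(self, small_index):
        parent = Proteoform("CIQRHRSCRKSSECCGCSVCQCNLFGQNCQCKSGGLIAC")
        pep = [p for p in digest(parent, "trypsin", 0)
               if p.sequence == "SSECCGCSVCQCNLFGQNCQCK"][0]
        form = apply_modifications(pep, FIXED_CAM, None, 0)[0]
        s = _spectrum_for(form)
        off = Spectrum(s.id, s.precursor_mz * (1 + 50e-6),
                       s.precursor_charge, s.peaks)
        assert match_spectrum(off, small_index, prec_tol_ppm=10) == []

    def test_score_invariances(self, small_index):
        parent = Proteoform("CWWHHKCNNCLLTTRCPPQQCAAC")
        pep = digest(parent, "trypsin", 1)[0]
        form = apply_modifications(pep, FIXED_CAM, None, 0)[0]
        s = _spectrum_for(form, noise=10)
        base, n = score_match(s, form, 0.02)
        scaled = Spectrum(s.id, s.precursor_mz, s.precursor_charge,
                          tuple((m, 7.5 * i) for m, i in s.peaks))
        shuffled_peaks = list(s.peaks)[::-1]
        shuffled = Spectrum(s.id, s.precursor_mz, s.precursor_charge,
                            tuple(sorted(shuffled_peaks)))
        assert score_match(scaled, form, 0.02)[0] == pytest.approx(base)
        assert score_match(shuffled, form, 0.02)[0] == pytest.approx(base)


class TestFdr:
    def _psm(self, score, decoy, i):
        pep = ProteolyticPeptide("AAK", 1, 3, 0)
        return PSM(f"s{i}", "acc", Peptidoform(pep), score, 1, decoy)

    def test_clear_separation_all_pass(self):
        psms = [self._psm(10.0, False, i) for i in range(99)]
        psms.append(self._psm(5.0, True, 99))
        accepted = target_decoy_fdr(psms, 0.01)
        assert len(accepted) == 99

    def test_interleaved_equal_scores_none_pass(self):
        psms = []
        for i in range(50):
            psms.append(self._psm(1.0, False, 2 * i))
            psms.append(self._psm(1.0, True, 2 * i + 1))
        assert target_decoy_fdr(psms, 0.01) == []

    def test_q_values_monotone_in_score(self):
        rng = np.random.default_rng(3)
        psms = [self._psm(float(rng.normal()), bool(rng.random() < 0.5), i)
                for i in range(200)]
        target_decoy_fdr(psms, 0.01)
        ranked = sorted(psms, key=lambda p: -p.score)
        qs = [p.q_value for p in ranked]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))

    def test_empirical_fdr_on_mixed_run(self, annotated_precursors):
        """200 true + 200 noise spectra: observed FDR <= 2% at alpha = 1%."""
        precursors = annotated_precursors[:100]
        db = build_search_db(precursors)
        index = PeptidoformIndex(db, "trypsin", 1, fixed=FIXED_CAM)
        forms = []
        for entry in db.entries:
            if entry.is_decoy or entry.kind != "mature":
                continue
            for pep in digest(Proteoform(entry.sequence), "trypsin", 1):
                if 6 <= len(pep) <= 30:
                    forms.extend(apply_modifications(pep, FIXED_CAM, None, 0))
        forms = forms[:200]
        assert len(forms) == 200
        spectra, truth = gen_msms_run(forms, seed=11, dropout=0.15,
                                      frag_noise_peaks=15)
        all_masses = [m for m, *_ in index._records]
        rng = np.random.default_rng(13)
        noise_masses = [float(all_masses[i]) for i in
                        rng.integers(0, len(all_masses), size=200)]
        noise = gen_noise_spectra(noise_masses, seed=13)
        psms = []
        for s in spectra + noise:
            psms.extend(match_spectrum(s, index))
        accepted = target_decoy_fdr(psms, 0.01)
        assert accepted
        false = [p for p in accepted
                 if p.spectrum_id not in truth
                 or p.peptidoform.sequence != truth[p.spectrum_id][0]]
        assert len(false) / len(accepted) <= 0.02

    def test_rank_one_rate_on_noise_free_spectra(self, annotated_precursors):
        """>= 98% of clean spectra identify their true peptide at rank 1."""
        precursors = annotated_precursors[:100]
        db = build_search_db(precursors)
        index = PeptidoformIndex(db, "trypsin", 1, fixed=FIXED_CAM)
        forms = []
        for entry in db.entries:
            if entry.is_decoy or entry.kind != "mature":
                continue
            for pep in digest(Proteoform(entry.sequence), "trypsin", 1):
                if 6 <= len(pep) <= 30:
                    forms.extend(apply_modifications(pep, FIXED_CAM, None, 0))
        forms = forms[:200]
        spectra, truth = gen_msms_run(forms, seed=29, dropout=0.0,
                                      frag_noise_peaks=0)
        rank1 = 0
        for s in spectra:
            psms = match_spectrum(s, index)
            rank1 += bool(psms) and psms[0].peptidoform.sequence == \
                truth[s.id][0]
        assert rank1 >= 0.98 * len(spectra)

    def test_conservative_on_pure_noise(self, annotated_precursors):
        """Null simulation (n = 1000): accepted fraction <= alpha + 2 SE."""
        precursors = annotated_precursors[:40]
        db = build_search_db(precursors)
        index = PeptidoformIndex(db, "trypsin", 1, fixed=FIXED_CAM)
        masses = [m for m, *_ in index._records]
        rng = np.random.default_rng(7)
        chosen = [float(masses[i]) for i in
                  rng.integers(0, len(masses), size=1000)]
        noise = gen_noise_spectra(chosen, seed=19)
        psms = []
        for s in noise:
            psms.extend(match_spectrum(s, index))
        accepted = target_decoy_fdr(psms, 0.01)
        alpha = 0.01
        se = np.sqrt(alpha * (1 - alpha) / 1000)
        assert len(accepted) / 1000 <= alpha + 2 * se


class TestCoverage:
    def _psm_at(self, seq, start, end, i=0):
        pep = ProteolyticPeptide(seq, start, end, 0)
        return PSM(f"s{i}", "acc", Peptidoform(pep), 1.0, 1, False)

    def test_union_of_overlapping_peptides(self, tbo_mature):
        psms = [self._psm_at("KSSECCGCSVCQCNLFGQNCQCK", 10, 32),
                self._psm_at("CCGCSVCQCNLFGQNCQCKSGGLIAC", 14, 39, 1)]
        intervals, counts = sequence_coverage(psms, tbo_mature)
        assert intervals == [(10, 39)]
        covered = sum(b - a + 1 for a, b in intervals)
        assert covered == 30

    def test_empty(self):
        assert sequence_coverage([], "AAAA") == ([], {})

    def test_duplicate_psms_increment_counts_only(self):
        psms = [self._psm_at("AAK", 1, 3, i) for i in range(3)]
        intervals, counts = sequence_coverage(psms, "AAKW")
        assert intervals == [(1, 3)]
        assert counts[("AAK", 1, 3)] == 3
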