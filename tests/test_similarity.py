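"""Whole-sequence, positional and TF-IDF similarity methods."""

import math

import numpy as np
import pytest

from pepsim.chem import Peptide
from pepsim.similarity import (
    SimilarityMatrix,
    cross_family_averages,
    full_similarity,
    manual_tfidf_cosine,
    pairwise_matrix,
    positional_similarity,
    tfidf_cosine,
)


def pep(pid: str, seq: str, family=None) -> Peptide:
    return Peptide(id=pid, residues=seq, family=family)


class TestFullSimilarity:
    def test_identical_sequence_scores_one(self, small_params):
        assert full_similarity("CGGSGGC", "CGGSGGC", small_params) == 1.0

    def test_symmetry(self, small_params):
        ab = full_similarity("CGGSGGC", "CGSGGSGC", small_params)
        ba = full_similarity("CGSGGSGC", "CGGSGGC", small_params)
        assert ab == ba

    def test_estimate_tracks_exact_oracle(self, oracle_params):
        est = full_similarity("CGGSGGC", "CGSGGSGC", oracle_params)
        exact = full_similarity("CGGSGGC", "CGSGGSGC", oracle_params, exact=True)
        assert est == pytest.approx(exact, abs=0.05)

    def test_bounded_in_unit_interval(self, small_params):
        s = full_similarity("CTTRRPYLVCWL", "CYKLAEGDKYYIC", small_params)
        assert 0.0 <= s <= 1.0


class TestPositionalSimilarity:
    def test_twelve_positions_for_cx10c(self, small_params):
        profile = positional_similarity(
            "CPANAAAPAAAC", "CHPQAAAAAAAC", small_params
        )
        assert len(profile.values) == 12
        assert list(profile.positions) == list(range(1, 13))

    def test_identical_residues_short_circuit_to_one(self, small_params):
        profile = positional_similarity("CPAN", "CPGN", small_params)
        assert profile.values[0] == 1.0
        assert profile.values[1] == 1.0
        assert profile.values[3] == 1.0
        assert profile.values[2] < 1.0

    def test_self_profile_all_ones(self, small_params):
        profile = positional_similarity("CQPHPGQTC", "CQPHPGQTC", small_params)
        assert (profile.values == 1.0).all()

    def test_gly_vs_ala_matches_exact_oracle(self, oracle_params):
        est = positional_similarity("G", "A", oracle_params).values[0]
        exact = positional_similarity("G", "A", oracle_params, exact=True).values[0]
        assert est == pytest.approx(exact, abs=0.05)

    def test_length_mismatch_reports_both_lengths(self, small_params):
        with pytest.raises(ValueError, match="7.*9|9.*7"):
            positional_similarity(
                pep("a", "CGGSGGC"), pep("b", "CQPHPGQTC"), small_params
            )


class TestTfidfCosine:
    def test_identical_sequences_score_one(self):
        m = tfidf_cosine([pep("a", "ACD"), pep("b", "ACD"), pep("c", "GGG")])
        assert m.loc("a", "b") == pytest.approx(1.0)

    def test_disjoint_residues_score_zero(self):
        m = tfidf_cosine([pep("a", "AAA"), pep("b", "GGG")])
        assert m.loc("a", "b") == pytest.approx(0.0)

    def test_toy_corpus_matches_hand_formula(self):
        """Three-sequence corpus against direct idf/cosine arithmetic."""
        corpus = ["AAG", "AGG", "CCC"]
        panel = [pep(s, s) for s in corpus]
        m = tfidf_cosine(panel)
        for i, a in enumerate(corpus):
            for j, b in enumerate(corpus):
                assert m.values[i, j] == pytest.approx(
                    manual_tfidf_cosine(a, b, corpus), abs=1e-12
                )

    def test_matches_sklearn_vectorizer(self):
        """Independent oracle: scikit-learn's TfidfVectorizer with
        character tokens and default smooth-idf/L2 settings."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.feature_extraction.text import TfidfVectorizer
        from sklearn.metrics.pairwise import cosine_similarity

        seqs = ["CGGSGGC", "CGSGGSGC", "CQPHPGQTC", "CTTRRPYLVCWL"]
        ours = tfidf_cosine([pep(s, s) for s in seqs]).values
        vec = TfidfVectorizer(analyzer="char", lowercase=False)
        theirs = cosine_similarity(vec.fit_transform(seqs))
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            tfidf_cosine([])


class TestPairwiseMatrix:
    def test_symmetric_unit_diagonal(self, small_params):
        panel = [pep("a", "CGGSGGC"), pep("b", "CGSGGSGC"), pep("c", "CQPHPGQTC")]
        for method in ("full_map4", "tfidf_cosine"):
            m = pairwise_matrix(panel, method, small_params)
            assert (m.values == m.values.T).all()
            assert np.allclose(np.diag(m.values), 1.0)
            assert ((m.values >= 0) & (m.values <= 1)).all()

    def test_entries_match_single_calls(self, small_params):
        panel = [pep("a", "CGGSGGC"), pep("b", "CGSGGSGC")]
        m = pairwise_matrix(panel, "full_map4", small_params)
        assert m.loc("a", "b") == full_similarity("CGGSGGC", "CGSGGSGC", small_params)

    def test_positional_mean_entry_is_profile_mean(self, small_params):
        panel = [pep("a", "CPAN"), pep("b", "CHGN")]
        m = pairwise_matrix(panel, "positional_mean", small_params)
        profile = positional_similarity(panel[0], panel[1], small_params)
        assert m.loc("a", "b") == pytest.approx(profile.mean())

    def test_duplicate_ids_rejected(self, small_params):
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_matrix([pep("a", "GG"), pep("a", "GA")], "full_map4", small_params)

    def test_repeated_sequence_all_ones(self, small_params):
        panel = [pep("a", "CGGSGGC"), pep("b", "CGGSGGC")]
        m = pairwise_matrix(panel, "full_map4", small_params)
        assert (m.values == 1.0).all()


class TestCrossFamilyAverages:
    def toy_matrix(self):
        return SimilarityMatrix(
            labels=("s1", "s2", "h1"),
            values=np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]]),
            method="full_map4",
        )

    def test_two_by_two(self):
        m = SimilarityMatrix(
            labels=("a", "b"),
            values=np.array([[1.0, 0.4], [0.4, 1.0]]),
            method="full_map4",
        )
        comp = cross_family_averages(m, ["a"], ["b"])
        assert comp.cross_mean == {"a": 0.4, "b": 0.4}
        assert comp.within_mean == {"a": None, "b": None}

    def test_diagonal_never_contributes(self):
        comp = cross_family_averages(self.toy_matrix(), ["s1", "s2"], ["h1"])
        assert comp.cross_mean["s1"] == pytest.approx(0.2)
        assert comp.cross_mean["h1"] == pytest.approx(0.3)
        assert comp.within_mean["s1"] == pytest.approx(0.6)
        assert comp.within_mean["h1"] is None

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            cross_family_averages(self.toy_matrix(), ["s1"], ["s1", "h1"])

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError):
            cross_family_averages(self.toy_matrix(), ["s1"], ["nope"])
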