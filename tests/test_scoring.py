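"""Local alignment scoring: DP vs exhaustive enumeration, gaps, matrix I/O."""

import itertools

import numpy as np
import pytest

from raretail.null_models import Alphabet
from raretail.oracles import enumerate_alignments
from raretail.scoring import (
    Alignment,
    GapPenalty,
    MatrixFormatError,
    PositionSpecificScheme,
    ScoringMatrix,
    blosum62,
    gap_lengths,
    load_matrix,
    save_matrix,
    score_alignment,
    smith_waterman_score,
    smith_waterman_traceback,
    tm_synthetic_matrix,
)
from raretail.testing import toy_alphabet, toy_matrix, toy_scheme


class TestGapPenalty:
    def test_default_convention_charges_open_plus_length(self):
        g = GapPenalty(12, 1)
        assert g.cost(1) == 13
        assert g.cost(3) == 15

    def test_alternative_convention(self):
        g = GapPenalty(12, 1, "open_plus_len_minus_1")
        assert g.cost(1) == 12
        assert g.cost(3) == 14

    def test_negative_penalties_rejected(self):
        with pytest.raises(ValueError):
            GapPenalty(-1, 1)


class TestSmithWaterman:
    def test_empty_sequences_score_zero(self):
        scheme = toy_scheme()
        assert smith_waterman_score("", "AB", scheme) == 0
        assert smith_waterman_score("AB", "", scheme) == 0

    def test_self_alignment_lower_bound(self):
        scheme = toy_scheme(match=4, mismatch=-2)
        for seq in ("A", "ABAB", "BBBAAB"):
            assert smith_waterman_score(seq, seq, scheme) >= 4 * len(seq)

    def test_exhaustive_two_letter_up_to_4mers(self):
        scheme = toy_scheme(alphabet_size=2)
        seqs = [
            "".join(s)
            for l in range(0, 5)
            for s in itertools.product("AB", repeat=l)
        ]
        for x in seqs:
            for y in seqs:
                expected = enumerate_alignments(x, y, scheme) if x and y else 0
                assert smith_waterman_score(x, y, scheme) == expected, (x, y)

    def test_random_three_letter_6mers_match_enumeration(self, rng):
        scheme = toy_scheme(alphabet_size=3, match=3, mismatch=-2, gap_open=3)
        for _ in range(500):
            x = rng.integers(0, 3, size=6)
            y = rng.integers(0, 3, size=6)
            assert smith_waterman_score(x, y, scheme) == enumerate_alignments(
                x, y, scheme
            )

    def test_monotone_in_sequence_extension(self, rng):
        scheme = toy_scheme(alphabet_size=3)
        for _ in range(50):
            x = rng.integers(0, 3, size=5)
            y = rng.integers(0, 3, size=5)
            s = smith_waterman_score(x, y, scheme)
            assert smith_waterman_score(np.append(x, 0), y, scheme) >= s
            assert smith_waterman_score(x, np.append(y, 1), scheme) >= s

    def test_region_matrix_equal_to_default_is_identity(self, rng):
        ab = toy_alphabet(3)
        m = toy_matrix(ab, 2, -1)
        plain = PositionSpecificScheme(m, GapPenalty(2, 1))
        split = PositionSpecificScheme(
            m, GapPenalty(2, 1), region_matrix=m, query_regions=[(2, 4)]
        )
        for _ in range(200):
            x = rng.integers(0, 3, size=6)
            y = rng.integers(0, 3, size=6)
            assert smith_waterman_score(x, y, plain) == smith_waterman_score(
                x, y, split
            )

    def test_region_matrix_changes_scores_inside_region(self):
        ab = toy_alphabet(2)
        weak = toy_matrix(ab, 1, -2)
        strong = toy_matrix(ab, 5, -2)
        scheme = PositionSpecificScheme(
            weak, GapPenalty(4, 2), region_matrix=strong, query_regions=[(1, 2)]
        )
        # matches on rows 1-2 score 5, elsewhere 1
        assert smith_waterman_score("AA", "AA", scheme) == 10
        assert smith_waterman_score("AAAA", "AAAA", scheme) == 12

    def test_adding_constant_never_decreases_score(self, rng):
        ab = toy_alphabet(2)
        base = toy_matrix(ab, 2, -1)
        shifted = ScoringMatrix(ab, base.scores + 1, "shifted")
        s1 = PositionSpecificScheme(base, GapPenalty(2, 1))
        s2 = PositionSpecificScheme(shifted, GapPenalty(2, 1))
        for _ in range(50):
            x = rng.integers(0, 2, size=5)
            y = rng.integers(0, 2, size=6)
            assert smith_waterman_score(x, y, s2) >= smith_waterman_score(x, y, s1)

    def test_traceback_alignment_scores_its_own_score(self, rng):
        scheme = toy_scheme(alphabet_size=3, match=3, mismatch=-1, gap_open=2)
        for _ in range(100):
            x = rng.integers(0, 3, size=6)
            y = rng.integers(0, 3, size=6)
            best, aln = smith_waterman_traceback(x, y, scheme)
            assert best == smith_waterman_score(x, y, scheme)
            if aln.pairs:
                assert score_alignment(x, y, aln, scheme) == best


class TestScoreAlignment:
    def test_empty_alignment_scores_zero(self):
        scheme = toy_scheme()
        assert score_alignment("AB", "AB", Alignment(()), scheme) == 0

    def test_single_pair(self):
        scheme = toy_scheme(match=2, mismatch=-1)
        assert score_alignment("A", "A", Alignment(((1, 1),)), scheme) == 2
        assert score_alignment("A", "B", Alignment(((1, 1),)), scheme) == -1

    def test_internal_gaps_charged_flanks_free(self):
        scheme = toy_scheme(match=2, mismatch=-1, gap_open=2, gap_extend=1)
        # pairs (1,2) and (3,3): one unpaired query position between them
        aln = Alignment(((1, 2), (3, 3)))
        assert score_alignment("ABA", "BAA", aln, scheme) == 2 + 2 - 3

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            Alignment(((1, 2), (2, 1)))

    def test_optimum_matches_sw_on_toys(self, rng):
        scheme = toy_scheme(alphabet_size=2)
        for _ in range(30):
            x = rng.integers(0, 2, size=4)
            y = rng.integers(0, 2, size=4)
            best = 0
            for k in range(1, 5):
                for rows in itertools.combinations(range(1, 5), k):
                    for cols in itertools.combinations(range(1, 5), k):
                        s = score_alignment(
                            x, y, Alignment(tuple(zip(rows, cols))), scheme
                        )
                        best = max(best, s)
            assert best == smith_waterman_score(x, y, scheme)


class TestGapLengths:
    def test_worked_example_two_gaps(self):
        # the classic paired display with gaps of lengths two and three
        assert gap_lengths("QGEGGDA---WC", "QG--GDATTTWC") == [2, 3]

    def test_no_gaps(self):
        assert gap_lengths("ABC", "ABD") == []

    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError, match="both rows"):
            gap_lengths("A-C", "A-C")

    def test_matches_run_length_encoding(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            gx = rng.random(n) < 0.25
            gy = (rng.random(n) < 0.25) & ~gx
            ax = "".join("-" if g else "A" for g in gx)
            ay = "".join("-" if g else "A" for g in gy)
            expected = sorted(
                len(list(grp))
                for mask in (gx, gy)
                for v, grp in itertools.groupby(mask)
                if v
            )
            assert gap_lengths(ax, ay) == expected


class TestMatrixIO:
    def test_blosum62_reference_entries(self):
        m = blosum62()
        # cross-checked against the canonical published matrix
        assert m.score("A", "A") == 4
        assert m.score("W", "W") == 11
        assert m.score("A", "W") == -3
        assert m.score("E", "K") == 1

    def test_blosum62_matches_biopython_reference(self):
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load("BLOSUM62")
        m = blosum62()
        for a in "ACDW":
            for b in "ACDW":
                assert m.score(a, b) == int(ref[a][b])

    def test_negative_expected_score_under_background(self):
        from raretail.null_models import swissprot_frequencies

        bg = swissprot_frequencies()
        assert blosum62().expected_score(bg.freqs) < 0
        assert tm_synthetic_matrix().expected_score(bg.freqs) < 0

    def test_tm_matrix_is_non_symmetric(self):
        m = tm_synthetic_matrix()
        assert not np.array_equal(m.scores, m.scores.T)

    def test_round_trip(self, tmp_path):
        m = blosum62()
        p = tmp_path / "m.mat"
        save_matrix(m, p)
        again = load_matrix(p)
        assert np.array_equal(again.scores, m.scores)

    def test_ragged_file_rejected(self, tmp_path):
        p = tmp_path / "bad.mat"
        p.write_text("   A  B\nA  1\nB  0  1\n")
        with pytest.raises(MatrixFormatError):
            load_matrix(p)

    def test_non_integer_entries_rejected(self, tmp_path):
        p = tmp_path / "float.mat"
        p.write_text("   A  B\nA  1.5  0\nB  0  1\n")
        with pytest.raises(MatrixFormatError):
            load_matrix(p)


class TestSchemeValidation:
    def test_overlapping_regions_rejected(self):
        ab = toy_alphabet(2)
        m = toy_matrix(ab)
        with pytest.raises(ValueError, match="overlap"):
            PositionSpecificScheme(
                m, GapPenalty(2, 1), region_matrix=m, query_regions=[(1, 4), (3, 6)]
            )

    def test_interval_outside_query_rejected(self):
        ab = toy_alphabet(2)
        m = toy_matrix(ab)
        scheme = PositionSpecificScheme(
            m, GapPenalty(2, 1), region_matrix=m, query_regions=[(5, 9)]
        )
        with pytest.raises(ValueError, match="outside"):
            scheme.row_matrix_index(3)

    def test_row_index_is_one_based_inclusive(self):
        ab = toy_alphabet(2)
        m = toy_matrix(ab)
        scheme = PositionSpecificScheme(
            m, GapPenalty(2, 1), region_matrix=m, query_regions=[(2, 3)]
        )
        assert scheme.row_matrix_index(4).tolist() == [0, 1, 1, 0]
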