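"""Substitution-matrix handling and the two-pass PB sequence aligner."""

import random

import numpy as np
import pytest

from pbsuper import (
    Anchor,
    AnchorParams,
    anchored_align,
    find_anchors,
    global_align,
    load_matrix,
)
from pbsuper.align import AlignmentError, SubstitutionMatrix, score_alignment
from pbsuper.pb import PB_LETTERS

from _oracles import brute_force_align_score
from conftest import random_pb_string


class TestSubstitutionMatrix:
    def test_bundled_default_is_valid(self, matrix):
        assert matrix.scores.shape == (16, 16)
        assert np.allclose(matrix.scores, matrix.scores.T)
        off = matrix.scores - np.diag(np.diag(matrix.scores))
        assert np.all(np.diag(matrix.scores) >= off.max(axis=1))

    def test_user_identity_matrix_accepted(self, tmp_path):
        p = tmp_path / "id.tsv"
        rows = ["  " + "  ".join(PB_LETTERS)]
        for i, c in enumerate(PB_LETTERS):
            rows.append(c + " " + " ".join("1" if j == i else "0" for j in range(16)))
        p.write_text("\n".join(rows) + "\n")
        m = load_matrix(p)
        assert m.score("a", "a") == 1.0
        assert m.score("a", "b") == 0.0

    def test_wrong_dimensions_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        rows = ["  " + "  ".join(PB_LETTERS)]
        for i, c in enumerate(PB_LETTERS[:15]):  # one row short
            rows.append(c + " " + " ".join("1" if j == i else "0" for j in range(16)))
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(AlignmentError, match="16"):
            load_matrix(p)

    def test_asymmetric_matrix_rejected(self):
        s = np.eye(16)
        s[0, 1] = 0.5
        with pytest.raises(AlignmentError, match="symmetric"):
            SubstitutionMatrix(scores=s)

    def test_z_columns_score_neutral(self, matrix):
        assert matrix.score("Z", "m") == 0.0
        assert matrix.score("Z", "Z") == 0.0


class TestGlobalAlign:
    def test_identical_strings_align_without_gaps(self, matrix):
        aln = global_align("mmmmdd", "mmmmdd", matrix)
        assert aln.n_aligned == 6
        assert all(i == j for i, j in aln.columns)
        expected = 4 * matrix.score("m", "m") + 2 * matrix.score("d", "d")
        assert aln.score == pytest.approx(expected)

    def test_empty_sequence_rejected(self, matrix):
        with pytest.raises(AlignmentError):
            global_align("mmm", "", matrix)

    def test_single_substitution_column(self):
        # identity matrix: substituting (score 0) beats two gaps (2 * open)
        ident = SubstitutionMatrix(scores=np.eye(16))
        aln = global_align("m", "d", ident)
        assert aln.columns == [(0, 0)]
        assert aln.score == pytest.approx(ident.score("m", "d"))

    def test_matches_brute_force_on_short_random_pairs(self, matrix):
        rnd = random.Random(11)
        for _ in range(120):
            a = random_pb_string(rnd, rnd.randint(1, 8))
            b = random_pb_string(rnd, rnd.randint(1, 8))
            dp = global_align(a, b, matrix).score
            bf = brute_force_align_score(a, b, matrix.score,
                                         matrix.gap_open, matrix.gap_extend)
            assert dp == pytest.approx(bf, abs=1e-9), (a, b)

    def test_traceback_score_is_self_consistent(self, matrix):
        rnd = random.Random(5)
        for _ in range(50):
            a = random_pb_string(rnd, rnd.randint(2, 30))
            b = random_pb_string(rnd, rnd.randint(2, 30))
            aln = global_align(a, b, matrix)
            assert score_alignment(aln.columns, a, b, matrix) == pytest.approx(aln.score)

    def test_score_is_symmetric_and_transpose_is_optimal(self, matrix):
        rnd = random.Random(23)
        for _ in range(60):
            a = random_pb_string(rnd, rnd.randint(1, 20))
            b = random_pb_string(rnd, rnd.randint(1, 20))
            fwd = global_align(a, b, matrix)
            rev = global_align(b, a, matrix)
            assert fwd.score == pytest.approx(rev.score, abs=1e-9)
            transposed = [(j, i) for i, j in rev.columns]
            assert score_alignment(transposed, a, b, matrix) == pytest.approx(fwd.score)

    def test_harsher_gaps_never_add_gap_columns(self, matrix):
        rnd = random.Random(37)
        for _ in range(40):
            a = random_pb_string(rnd, rnd.randint(3, 25))
            b = random_pb_string(rnd, rnd.randint(3, 25))
            soft = global_align(a, b, matrix, gap_open=-2.0, gap_extend=-0.25)
            hard = global_align(a, b, matrix, gap_open=-8.0, gap_extend=-2.0)
            gaps = lambda aln: sum(1 for i, j in aln.columns if i is None or j is None)
            assert gaps(hard) <= gaps(soft)


class TestAnchors:
    def test_identical_sequences_give_single_spanning_anchor(self, matrix):
        s = "mmmmmddddcafklmmmmmm"
        anchors = find_anchors(s, s, matrix)
        assert len(anchors) == 1
        assert anchors[0].start_i == anchors[0].start_j == 0
        assert anchors[0].length == len(s)

    def test_dissimilar_sequences_give_no_anchors(self, matrix):
        # per-column threshold is 80% of the max diagonal; make every
        # letter pair score far below it
        anchors = find_anchors("mmmmmmmm", "dddddddd", matrix)
        assert anchors == []

    def test_planted_block_recovered_inside_anchor(self, matrix):
        rnd = random.Random(2)
        block = "mfklopcadb"
        f1 = random_pb_string(rnd, 12, with_z=False)
        f2 = random_pb_string(rnd, 9, with_z=False)
        g1 = random_pb_string(rnd, 7, with_z=False)
        g2 = random_pb_string(rnd, 14, with_z=False)
        s1, s2 = f1 + block + f2, g1 + block + g2
        anchors = find_anchors(s1, s2, matrix)
        covering = [
            a for a in anchors
            if a.start_i <= len(f1) and a.end_i >= len(f1) + len(block)
            and a.start_j - a.start_i == len(g1) - len(f1)
        ]
        assert covering, f"no anchor covers the planted block: {anchors}"

    def test_z_positions_never_seed_anchors(self, matrix):
        s = "ZZZZZZZZZZ"
        assert find_anchors(s, s, matrix) == []


class TestAnchoredAlign:
    def test_empty_anchor_list_reduces_to_global(self, matrix):
        rnd = random.Random(17)
        for _ in range(100):
            a = random_pb_string(rnd, rnd.randint(1, 15))
            b = random_pb_string(rnd, rnd.randint(1, 15))
            plain = global_align(a, b, matrix)
            anchored = anchored_align(a, b, matrix, [])
            assert anchored.columns == plain.columns
            assert anchored.score == pytest.approx(plain.score, abs=1e-9)

    def test_anchors_covering_everything_are_returned_verbatim(self, matrix):
        s = "mmmmmmmmmm"
        anchor = Anchor(start_i=0, start_j=0, length=10, segment_score=60.0)
        aln = anchored_align(s, s, matrix, [anchor])
        assert aln.columns == [(k, k) for k in range(10)]

    def test_inconsistent_anchors_rejected(self, matrix):
        bad = [
            Anchor(start_i=0, start_j=5, length=5, segment_score=30.0),
            Anchor(start_i=5, start_j=0, length=5, segment_score=30.0),  # crosses
        ]
        with pytest.raises(AlignmentError, match="anchor"):
            anchored_align("m" * 12, "m" * 12, matrix, bad)

    def test_planted_block_survives_completion(self, matrix):
        rnd = random.Random(4)
        block = "mfklopcadb"
        s1 = random_pb_string(rnd, 11, with_z=False) + block + \
            random_pb_string(rnd, 6, with_z=False)
        s2 = random_pb_string(rnd, 5, with_z=False) + block + \
            random_pb_string(rnd, 13, with_z=False)
        anchors = find_anchors(s1, s2, matrix)
        aln = anchored_align(s1, s2, matrix, anchors)
        pairs = set(aln.aligned_pairs())
        for k in range(len(block)):
            assert (11 + k, 5 + k) in pairs

    def test_stringent_pass_parameters_are_configurable(self, matrix):
        params = AnchorParams(weight=5.0, score_fraction=0.99, min_length=3)
        anchors = find_anchors("mmmm", "mmmm", matrix, params)
        assert anchors and anchors[0].length == 4
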