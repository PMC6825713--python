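"""GDT_TS, GDT_PB, PB identity and the aggregated score panel."""

import copy
import random

import numpy as np
import pytest

from pbsuper import (
    PairAlignment,
    PBSequence,
    build_backbone,
    encode_chain,
    gdt_pb,
    gdt_ts,
    helix_spec,
    pb_identity,
    score_panel,
    superpose_aligned,
)
from pbsuper.scores import GDT_THRESHOLDS
from pbsuper.superpose import RigidTransform

from _oracles import recount_gdt_pb
from conftest import random_pb_string, random_rigid


def identity_alignment(n):
    return PairAlignment(columns=[(i, i) for i in range(n)], score=0.0)


def two_block_pair(n=40, offset=20.0):
    """Chain B = chain A with its second half rigidly displaced by ``offset`` A.

    With ``offset`` far larger than every GDT threshold no rigid motion can
    reach pairs from both halves at once (a rotation large enough to carry
    any displaced pair home moves every coincident pair out of tolerance),
    so the best simultaneous fraction is exactly 1/2 per threshold.
    """
    a = build_backbone(helix_spec(n))
    b = copy.deepcopy(a)
    shift = np.array([offset, 0.0, 0.0])
    for r in b.residues[n // 2:]:
        r.coords_N = r.coords_N + shift
        r.coords_CA = r.coords_CA + shift
        r.coords_C = r.coords_C + shift
    return a, b


class TestGdtTs:
    def test_self_comparison_is_exactly_100(self, helix30):
        ts, fractions = gdt_ts(helix30, helix30, identity_alignment(30))
        assert ts == 100.0
        assert fractions == [1.0, 1.0, 1.0, 1.0]

    def test_thresholds_are_the_casp_set(self):
        assert GDT_THRESHOLDS == (1.0, 2.0, 4.0, 8.0)

    def test_two_block_geometry_counts_exactly(self):
        # blocks 200 A apart: no rigid motion can hold any displaced pair
        # within 8 A while keeping a majority of the coincident block, so
        # every fraction is exactly one half (direct counting)
        a, b = two_block_pair(n=40, offset=200.0)
        ts, fractions = gdt_ts(a, b, identity_alignment(40))
        assert fractions == [0.5, 0.5, 0.5, 0.5]
        assert ts == 50.0

    def test_two_block_10A_compromise_covers_loosest_threshold(self):
        # a 10 A displacement: the compromise fit leaves both halves at
        # ~5 A, inside 8 A, so the loosest fraction reaches 1.0; tighter
        # thresholds keep at least the coincident half, and transforms
        # pivoting near the junction may legitimately capture more
        a, b = two_block_pair(n=40, offset=10.0)
        ts, fractions = gdt_ts(a, b, identity_alignment(40))
        assert fractions[3] == 1.0
        assert all(0.5 <= f <= 1.0 for f in fractions)
        assert ts == pytest.approx(100 * np.mean(fractions))

    def test_fractions_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        from pbsuper import perturb

        for seed in range(5):
            a = build_backbone(helix_spec(25))
            b = perturb(a, sigma=float(rng.uniform(0.3, 2.0)), seed=seed)
            _, fractions = gdt_ts(a, b, identity_alignment(25))
            assert all(f1 <= f2 + 1e-12 for f1, f2 in zip(fractions, fractions[1:]))

    def test_invariant_under_rigid_motion_of_either_structure(self, helix30):
        rng = np.random.default_rng(13)
        from pbsuper import perturb

        b = perturb(helix30, 0.8, seed=3)
        ts0, fr0 = gdt_ts(helix30, b, identity_alignment(30))
        Q, t = random_rigid(rng)
        moved = copy.deepcopy(b)
        tf = RigidTransform(rotation=Q, translation=t)
        for r in moved.residues:
            r.coords_N = tf.apply(r.coords_N[None])[0]
            r.coords_CA = tf.apply(r.coords_CA[None])[0]
            r.coords_C = tf.apply(r.coords_C[None])[0]
        ts1, fr1 = gdt_ts(helix30, moved, identity_alignment(30))
        assert fr0 == fr1
        assert ts0 == pytest.approx(ts1, abs=1e-9)


class TestGdtPb:
    def test_identical_strings_score_one(self, matrix):
        s = PBSequence("ZZmmmmddddklZZ")
        assert gdt_pb(s, s, identity_alignment(len(s)), matrix) == 1.0

    def test_worst_columns_score_zero(self, matrix):
        # find the letter pair with the matrix minimum and align only those
        idx = np.unravel_index(np.argmin(matrix.scores), matrix.scores.shape)
        from pbsuper.pb import PB_LETTERS

        x, y = PB_LETTERS[idx[0]], PB_LETTERS[idx[1]]
        a, b = PBSequence(x * 6), PBSequence(y * 6)
        assert gdt_pb(a, b, identity_alignment(6), matrix) == 0.0

    def test_all_z_columns_are_undefined(self, matrix):
        s = PBSequence("ZZZZ")
        assert gdt_pb(s, s, identity_alignment(4), matrix) is None

    def test_matches_recount_oracle_on_random_alignments(self, matrix):
        rnd = random.Random(31)
        lo = float(matrix.scores.min())
        for _ in range(50):
            n = rnd.randint(4, 30)
            a = PBSequence(random_pb_string(rnd, n))
            b = PBSequence(random_pb_string(rnd, n))
            pairs = sorted(rnd.sample(range(n), rnd.randint(3, n)))
            aln = PairAlignment(columns=[(i, i) for i in pairs], score=0.0)
            ours = gdt_pb(a, b, aln, matrix)
            oracle = recount_gdt_pb(a.letters, b.letters, aln.aligned_pairs(),
                                    matrix.score, lo)
            if oracle is None:
                assert ours is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)


class TestPanel:
    def test_self_comparison_panel(self, helix30, matrix):
        seq = encode_chain(helix30)
        aln = identity_alignment(30)
        rep = superpose_aligned(helix30, helix30, aln)
        panel = score_panel(helix30, helix30, seq, seq, aln, matrix, rep)
        assert panel.gdt_ts == 100.0
        assert panel.rmsd_all < 1e-9
        assert panel.pb_identity == 1.0
        assert panel.gdt_pb == 1.0

    def test_two_block_panel_reproduces_gdt(self, matrix):
        a, b = two_block_pair(n=40, offset=200.0)
        sa, sb = encode_chain(a), encode_chain(b)
        aln = identity_alignment(40)
        rep = superpose_aligned(a, b, aln)
        panel = score_panel(a, b, sa, sb, aln, matrix, rep)
        assert panel.gdt_ts == 50.0

    def test_serialization_round_trip(self, helix30, matrix):
        import json

        seq = encode_chain(helix30)
        aln = identity_alignment(30)
        rep = superpose_aligned(helix30, helix30, aln)
        panel = score_panel(helix30, helix30, seq, seq, aln, matrix, rep)
        d = json.loads(panel.to_json())
        assert d["schema"] == "pbsuper-scores/1"
        assert d["gdt_ts"] == 100.0
        assert "GDT_TS" in panel.to_text()

    def test_pb_identity_counts_matching_columns(self):
        a = PBSequence("ZZmmddZZ")
        b = PBSequence("ZZmdddZZ")
        assert pb_identity(a, b, identity_alignment(8)) == pytest.approx(3 / 4)
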