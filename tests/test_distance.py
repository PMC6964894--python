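import numpy as np
import pytest

import qtcmatch as q
from qtcmatch.errors import QTCMatchError, RosterMismatchError, ValidationError

from oracles import (
    cellwise_matrix_cost,
    exhaustive_alignment_cost,
    random_sequence,
)


def _subst_table(seq_a, seq_b, scheme):
    la, lb = len(seq_a), len(seq_b)
    return np.array(
        [[q.matrix_cost(seq_a[i], seq_b[j], scheme) for j in range(lb)]
         for i in range(la)]
    ).reshape(la, lb)


class TestCharacterDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("-", "-", 0), ("0", "0", 0), ("+", "+", 0),
         ("-", "0", 1), ("0", "+", 1), ("0", "-", 1), ("+", "0", 1),
         ("-", "+", 2), ("+", "-", 2)],
    )
    def test_chain_metric(self, a, b, expected):
        assert q.character_distance(a, b) == expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValidationError):
            q.character_distance("-", "x")

    def test_scheme_validation(self):
        with pytest.raises(ValidationError, match="symmetric"):
            q.CostScheme(np.array([[0, 1, 2], [2, 0, 1], [2, 1, 0]]))
        with pytest.raises(ValidationError, match="triangle"):
            q.CostScheme(np.array([[0, 1, 9], [1, 0, 1], [9, 1, 0]]))
        with pytest.raises(ValidationError, match="diagonal"):
            q.CostScheme(np.array([[1, 1, 2], [1, 0, 1], [2, 1, 0]]))


class TestMatrixCost:
    def test_identical_matrices_cost_zero(self, rng, scheme):
        seq = random_sequence(rng, 3)
        assert q.matrix_cost(seq[0], seq[0], scheme) == 0

    def test_single_chain_step_costs_one(self, scheme):
        a = random_sequence(np.random.default_rng(0), 1)
        codes_minus = a.codes.copy()
        codes_minus[0, 0, 0] = -1
        codes_zero = codes_minus.copy()
        codes_zero[0, 0, 0] = 0  # single cell differs by one chain step
        m1 = q.QTCSequence(a.objects, a.n_moving, a.pairs, codes_minus)[0]
        m2 = q.QTCSequence(a.objects, a.n_moving, a.pairs, codes_zero)[0]
        assert q.matrix_cost(m1, m2, scheme) == 1

    def test_matches_cellwise_oracle(self, rng, scheme):
        for n_static in (0, 2):
            sa = random_sequence(rng, 4, n_moving=3, n_static=n_static)
            sb = random_sequence(rng, 4, n_moving=3, n_static=n_static)
            for i in range(4):
                assert q.matrix_cost(sa[i], sb[i], scheme) == cellwise_matrix_cost(
                    sa[i], sb[i], q.character_distance
                )

    def test_roster_mismatch_rejected(self, rng, scheme):
        sa = random_sequence(rng, 1, n_moving=2)
        sb = random_sequence(rng, 1, n_moving=3)
        with pytest.raises(RosterMismatchError):
            q.matrix_cost(sa[0], sb[0], scheme)


class TestMaxMatrixCost:
    @pytest.mark.parametrize(
        "n_moving,n_static,expected",
        [(2, 0, 4),    # one pair, two characters, worst step 2
         (2, 4, 36),   # the two-players-plus-corners roster: 9 pairs
         (3, 1, 24)],  # three players and one anchor: 6 pairs
    )
    def test_pair_counting(self, n_moving, n_static, expected):
        assert q.max_matrix_cost(n_moving, n_static) == expected

    def test_no_moving_objects_rejected(self):
        with pytest.raises(ValidationError):
            q.max_matrix_cost(0, 3)


class TestLevenshtein:
    def test_self_distance_zero(self, rng, scheme):
        seq = random_sequence(rng, 7)
        assert q.levenshtein_distance(seq, seq, scheme) == 0

    def test_empty_vs_nonempty_is_forced_deletions(self, rng, scheme):
        seq = random_sequence(rng, 5)
        empty = q.empty_sequence(seq)
        c_max = q.max_matrix_cost(seq.n_moving, seq.n_static, scheme)
        assert q.levenshtein_distance(empty, seq, scheme) == 5 * c_max

    def test_one_duplicated_matrix_costs_one_indel(self, rng, scheme):
        seq = random_sequence(rng, 6)
        dup = q.QTCSequence(
            seq.objects, seq.n_moving, seq.pairs,
            np.concatenate([seq.codes[:3], seq.codes[2:]], axis=0),
        )
        c_max = q.max_matrix_cost(seq.n_moving, seq.n_static, scheme)
        got = q.levenshtein_distance(seq, dup, scheme)
        oracle = exhaustive_alignment_cost(_subst_table(seq, dup, scheme), c_max)
        assert got == oracle <= c_max

    def test_equals_exhaustive_enumeration_on_short_pairs(self, scheme):
        """DP distance equals full alignment enumeration, mixed rosters."""
        rng = np.random.default_rng(4242)
        checked = 0
        while checked < 220:
            n_moving = int(rng.integers(2, 4))
            n_static = int(rng.integers(0, 2))
            la, lb = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            sa = random_sequence(rng, la, n_moving, n_static)
            sb = random_sequence(rng, lb, n_moving, n_static)
            c_max = q.max_matrix_cost(n_moving, n_static, scheme)
            oracle = exhaustive_alignment_cost(_subst_table(sa, sb, scheme), c_max)
            assert q.levenshtein_distance(sa, sb, scheme) == oracle
            checked += 1

    def test_metric_axioms_on_random_triples(self, scheme):
        rng = np.random.default_rng(777)
        for _ in range(200):
            lengths = rng.integers(0, 7, size=3)
            a, b, c = (random_sequence(rng, int(n)) for n in lengths)
            dab = q.levenshtein_distance(a, b, scheme)
            dba = q.levenshtein_distance(b, a, scheme)
            dac = q.levenshtein_distance(a, c, scheme)
            dcb = q.levenshtein_distance(c, b, scheme)
            assert dab >= 0
            assert dab == dba
            assert dab <= dac + dcb
            assert (dab == 0) == (a == b)

    def test_appending_identical_matrices_never_increases_distance(self, scheme):
        rng = np.random.default_rng(55)
        for _ in range(30):
            sa = random_sequence(rng, int(rng.integers(1, 6)))
            sb = random_sequence(rng, int(rng.integers(1, 6)))
            extra = random_sequence(rng, 1)
            d0 = q.levenshtein_distance(sa, sb, scheme)
            sa2 = q.QTCSequence(sa.objects, sa.n_moving, sa.pairs,
                                np.concatenate([sa.codes, extra.codes]))
            sb2 = q.QTCSequence(sb.objects, sb.n_moving, sb.pairs,
                                np.concatenate([sb.codes, extra.codes]))
            assert q.levenshtein_distance(sa2, sb2, scheme) <= d0


class TestNormalizedDistance:
    def test_identical_sequences_give_zero(self, rng, scheme):
        seq = random_sequence(rng, 9)
        res = q.normalized_distance(seq, seq, scheme)
        assert res.raw_cost == 0 and res.normalized == 0.0

    def test_empty_vs_nonempty_gives_one(self, rng, scheme):
        seq = random_sequence(rng, 4)
        assert q.normalized_distance(q.empty_sequence(seq), seq, scheme).normalized == 1.0

    def test_both_empty_gives_zero(self, rng, scheme):
        seq = random_sequence(rng, 1)
        empty = q.empty_sequence(seq)
        assert q.normalized_distance(empty, empty, scheme).normalized == 0.0

    def test_random_pairs_stay_in_unit_interval(self, scheme):
        rng = np.random.default_rng(31337)
        for _ in range(300):
            la, lb = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            if la == 0 and lb == 0:
                continue
            sa = random_sequence(rng, la)
            sb = random_sequence(rng, lb)
            res = q.normalized_distance(sa, sb, scheme)
            assert 0.0 <= res.normalized <= 1.0
            assert res.raw_cost <= max(la, lb) * res.c_max


class TestPairwiseBaseline:
    def test_identical_sequences_cost_zero(self, rng, scheme):
        seq = random_sequence(rng, 5)
        assert q.pairwise_distance(seq, seq, scheme) == 0

    def test_unequal_lengths_rejected(self, rng, scheme):
        sa = random_sequence(rng, 3)
        sb = random_sequence(rng, 4)
        with pytest.raises(QTCMatchError):
            q.pairwise_distance(sa, sb, scheme)

    def test_levenshtein_never_exceeds_pairwise(self, scheme):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            sa = random_sequence(rng, n)
            sb = random_sequence(rng, n)
            assert q.levenshtein_distance(sa, sb, scheme) <= q.pairwise_distance(
                sa, sb, scheme
            )

    def test_speed_warped_pair_is_cheaper_under_levenshtein(self, scheme):
        """A pause early vs late along the same path misaligns the whole
        middle of the position-aligned comparison but costs only one
        insertion plus one deletion under the edit distance."""
        base = q.random_fragment(17, 2, 30, step_sigma=0.4)
        early = q.time_warp(base, [q.WarpSegment(2, 4, 2)])
        late = q.time_warp(base, [q.WarpSegment(26, 28, 2)])
        sa, sb = q.encode_sequence(early), q.encode_sequence(late)
        lev = q.levenshtein_distance(sa, sb, scheme)
        pw = q.pairwise_distance(sa, sb, scheme)
        assert 0 < lev < pw


class TestCutoff:
    def test_zero_threshold_on_distinct_sequences_exceeds(self, rng, scheme):
        sa = random_sequence(rng, 4)
        sb = random_sequence(rng, 4)
        assert q.levenshtein_distance(sa, sb, scheme) > 0
        assert q.levenshtein_with_cutoff(sa, sb, scheme, threshold=0) is None

    def test_generous_threshold_returns_exact_distance(self, rng, scheme):
        sa = random_sequence(rng, 6)
        sb = random_sequence(rng, 8)
        exact = q.levenshtein_distance(sa, sb, scheme)
        assert q.levenshtein_with_cutoff(sa, sb, scheme, threshold=exact) == exact

    def test_agrees_with_full_dp_whenever_not_exceeded(self, scheme):
        rng = np.random.default_rng(123)
        exceeded = returned = 0
        for _ in range(200):
            sa = random_sequence(rng, int(rng.integers(0, 8)))
            sb = random_sequence(rng, int(rng.integers(0, 8)))
            exact = q.levenshtein_distance(sa, sb, scheme)
            threshold = int(rng.integers(0, 40))
            got = q.levenshtein_with_cutoff(sa, sb, scheme, threshold=threshold)
            if exact <= threshold:
                assert got == exact
                returned += 1
            else:
                assert got is None
                exceeded += 1
        assert returned > 20 and exceeded > 20  # both branches exercised

    def test_negative_threshold_rejected(self, rng, scheme):
        sa = random_sequence(rng, 2)
        with pytest.raises(ValidationError):
            q.levenshtein_with_cutoff(sa, sa, scheme, threshold=-1)
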