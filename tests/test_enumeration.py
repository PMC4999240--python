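"""Reachability enumeration, pattern characterizations, word builders."""

from itertools import product

import numpy as np
import pytest

from noncommnet.counting import minimal_sequence_count, poly_bernoulli
from noncommnet.enumeration import (
    bfs_reachable,
    enumerate_connected_one_colorings,
    is_connected,
    is_lonesum,
    minimal_sequences_bruteforce,
    minimal_word_class_count,
    opposite_word,
    staircase_word,
    t2_constructive_word,
)
from noncommnet.models import (
    K,
    P,
    RatchetSpec,
    SeqSpec,
    apply_word,
    connectivity_matrix,
    zero_config,
)


class TestBfs:
    @pytest.mark.parametrize("n,m", [(2, 2), (2, 3), (3, 3), (4, 2)])
    def test_ratchet_count_is_poly_bernoulli(self, n, m):
        spec = RatchetSpec(n, m, 1, 1, 1)
        assert len(bfs_reachable(spec)) == poly_bernoulli(n, m)

    @pytest.mark.parametrize("n,count", [(1, 2), (2, 7), (3, 94)])
    def test_full_sequestration_counts(self, n, count):
        assert len(bfs_reachable(SeqSpec(n, reduced=False))) == count

    def test_empty_alphabet(self, ratchet22):
        start = (1, 0, 0, 1)
        r = bfs_reachable(ratchet22, start, alphabet=())
        assert r.configs == {start}

    def test_witness_words_replay(self, seq3_full):
        r = bfs_reachable(seq3_full)
        for cfg in list(r)[:50]:
            assert apply_word(zero_config(seq3_full), r.word_index[cfg], seq3_full) == cfg


class TestLonesum:
    @pytest.mark.parametrize(
        "A,expected",
        [
            ([[1, 0], [0, 1]], False),
            ([[0, 1], [1, 0]], False),
            ([[1, 1], [0, 1]], True),
            ([[0, 0], [0, 0]], True),
            ([[1, 0, 1], [1, 1, 1], [0, 0, 1]], True),
        ],
    )
    def test_examples(self, A, expected):
        assert is_lonesum(A) is expected

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            is_lonesum([[0, 2], [1, 0]])

    def test_exhaustive_3x3_count_matches_poly_bernoulli(self):
        count = sum(
            is_lonesum(np.array(bits).reshape(3, 3))
            for bits in product((0, 1), repeat=9)
        )
        assert count == poly_bernoulli(3, 3) == 230

    def test_reachable_iff_lonesum(self):
        # BFS reach of the 3x3 threshold-1 network = lonesum matrices, and
        # every lonesum matrix is produced by its staircase word
        spec = RatchetSpec(3, 3, 1, 1, 1)
        reached = {
            tuple(connectivity_matrix(c, spec).flatten()) for c in bfs_reachable(spec)
        }
        for bits in product((0, 1), repeat=9):
            A = np.array(bits).reshape(3, 3)
            if is_lonesum(A):
                assert bits in reached
                replay = apply_word(zero_config(spec), staircase_word(A), spec)
                assert tuple(connectivity_matrix(replay, spec).flatten()) == bits
            else:
                assert bits not in reached

    def test_staircase_word_rejects_forbidden(self):
        with pytest.raises(ValueError):
            staircase_word([[1, 0], [0, 1]])

    def test_staircase_word_trivial_cases(self):
        assert staircase_word([[0, 0], [0, 0]]) == ()
        assert staircase_word([[1, 1], [1, 1]]) == (K(2), K(1))


class TestThresholdTwo:
    def test_all_patterns_constructible_2x2(self):
        spec = RatchetSpec(2, 2, 1, 1, 2)
        for bits in product((0, 1), repeat=4):
            word = t2_constructive_word(np.array(bits).reshape(2, 2))
            cfg = apply_word(zero_config(spec), word, spec)
            assert tuple(1 if s == 2 else 0 for s in cfg) == bits

    def test_forbidden_t1_pattern_reachable(self):
        spec = RatchetSpec(2, 2, 1, 1, 2)
        word = t2_constructive_word([[1, 0], [0, 1]])
        cfg = apply_word(zero_config(spec), word, spec)
        assert tuple(1 if s == 2 else 0 for s in cfg) == (1, 0, 0, 1)


class TestConnectedColorings:
    def test_missing_pair_support_disconnects(self, seq4_reduced):
        # {0,1,3} and {0,1,4} both OFF force {0,1,3,4} OFF
        bits = [0, 0, 0, 0, 0, 1, 0]  # only {1,3,4} ON
        assert not is_connected(bits, seq4_reduced)

    def test_printed_configuration_is_connected(self, seq4_reduced):
        assert is_connected((0, 0, 1, 0, 0, 0, 1), seq4_reduced)

    def test_zero_is_connected(self, seq4_reduced):
        assert is_connected((0,) * 7, seq4_reduced)

    @pytest.mark.parametrize("n,count", [(2, 2), (3, 7), (4, 89)])
    def test_counts(self, n, count):
        assert len(enumerate_connected_one_colorings(SeqSpec(n))) == count

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_equals_reachable_one_colorings(self, n):
        spec = SeqSpec(n, reduced=True)
        reached = {
            c for c in bfs_reachable(spec).configs if all(s in (0, 1) for s in c)
        }
        assert reached == enumerate_connected_one_colorings(spec)


class TestOppositeWord:
    def test_zero_target_gives_empty_word(self, seq4_reduced):
        assert opposite_word((0,) * 7, seq4_reduced) == ()

    def test_disconnected_target_rejected(self, seq4_reduced):
        with pytest.raises(ValueError):
            opposite_word([0, 0, 0, 0, 0, 1, 0], seq4_reduced)

    @pytest.mark.parametrize("n", [3, 4])
    def test_replay_exhaustive(self, n):
        spec = SeqSpec(n, reduced=True)
        for bits in sorted(enumerate_connected_one_colorings(spec)):
            word = opposite_word(bits, spec)
            assert apply_word(zero_config(spec), word, spec) == tuple(bits)

    def test_all_on_replay(self):
        spec = SeqSpec(3, reduced=True)
        bits = (1, 1, 1)
        word = opposite_word(bits, spec)
        assert apply_word(zero_config(spec), word, spec) == bits


class TestMinimalSequences:
    def test_total_configurations_at_unit_connectivity(self):
        oracle = minimal_sequences_bruteforce(RatchetSpec(2, 2, 1, 1, 1))
        assert len(oracle) == poly_bernoulli(2, 2) == 14

    def test_trivial_network(self):
        oracle = minimal_sequences_bruteforce(RatchetSpec(1, 1, 1, 1, 1))
        assert set(oracle) == {(0,), (1,)}
        assert oracle[(0,)] == {()}
        assert oracle[(1,)] == {(K(1),)}

    def test_two_activators_suffice_at_double_connectivity(self):
        # with l_n = l_m = 2 in the 3x3 network, any two K's turn all
        # targets ON, so K1 K2 is a surviving minimal word
        spec = RatchetSpec(3, 3, 2, 2, 1)
        oracle = minimal_sequences_bruteforce(spec)
        all_on = (1,) * spec.n_targets
        assert all_on in oracle
        assert {len(w) for w in oracle[all_on]} == {2}
        assert (K(1), K(2)) in oracle[all_on]

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 2), (2, 3), (3, 3)])
    def test_word_classes_match_recursion(self, n, m):
        for l_n in range(1, n + 1):
            for l_m in range(1, m + 1):
                oracle = minimal_sequences_bruteforce(RatchetSpec(n, m, l_n, l_m, 1))
                assert minimal_word_class_count(oracle) == minimal_sequence_count(
                    n, m, l_n, l_m
                )

    def test_word_length_bounds(self):
        # no surviving word uses more than n-l_n+1 K's or m-l_m P's
        spec = RatchetSpec(3, 3, 2, 2, 1)
        for words in minimal_sequences_bruteforce(spec).values():
            for w in words:
                assert sum(a.kind == "K" for a in w) <= spec.n - spec.l_n + 1
                assert sum(a.kind == "P" for a in w) <= spec.m - spec.l_m
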