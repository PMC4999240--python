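"""Action semantics and wiring of the two model families."""

import numpy as np
import pytest

from noncommnet.models import (
    K,
    P,
    RatchetSpec,
    SeqSpec,
    apply_word,
    build_ratchet_targets,
    build_seq_targets,
    connectivity_matrix,
    ratchet_apply,
    seq_apply,
    zero_config,
)


class TestRatchetWiring:
    @pytest.mark.parametrize(
        "n, m, l_n, l_m, n_targets, per_pair",
        [
            (2, 2, 1, 1, 4, 1),
            (3, 3, 2, 2, 9, 4),
            (1, 1, 1, 1, 1, 1),
            (4, 2, 2, 1, 12, 3),
        ],
    )
    def test_target_counts(self, n, m, l_n, l_m, n_targets, per_pair):
        spec = RatchetSpec(n, m, l_n, l_m, 1)
        targets = build_ratchet_targets(spec)
        assert len(targets) == n_targets == spec.n_targets
        assert spec.targets_per_pair == per_pair
        # handshake: every K index appears in p_n targets, every P in p_m
        for i in range(1, n + 1):
            assert sum(i in t.k_set for t in targets) == spec.p_n
        for j in range(1, m + 1):
            assert sum(j in t.p_set for t in targets) == spec.p_m

    def test_targets_per_pair_shared(self):
        # each (K_i, P_j) pair shares exactly M targets
        spec = RatchetSpec(3, 3, 2, 2, 1)
        targets = build_ratchet_targets(spec)
        shared = [t for t in targets if 1 in t.k_set and 1 in t.p_set]
        assert len(shared) == spec.targets_per_pair == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=2, m=2, l_n=3, l_m=1),
            dict(n=2, m=2, l_n=1, l_m=5),
            dict(n=0, m=2),
            dict(n=2, m=2, T=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RatchetSpec(**kwargs)


class TestRatchetDynamics:
    def test_activation_then_deactivation_sequence(self, ratchet22):
        # K1 K2 P1 from zero leaves the second column ON: matrix 01 / 01
        traj = apply_word(
            zero_config(ratchet22), [K(1), K(2), P(1)], ratchet22, trajectory=True
        )
        mats = [connectivity_matrix(c, ratchet22).tolist() for c in traj]
        assert mats == [
            [[0, 0], [0, 0]],
            [[1, 1], [0, 0]],
            [[1, 1], [1, 1]],
            [[0, 1], [0, 1]],
        ]

    def test_empty_word_is_identity(self, ratchet22):
        cfg = (1, 0, 1, 0)
        assert apply_word(cfg, [], ratchet22) == cfg

    def test_saturation_idempotence(self, ratchet22):
        once = ratchet_apply(zero_config(ratchet22), K(1), ratchet22)
        assert ratchet_apply(once, K(1), ratchet22) == once

    def test_threshold_two_order_dependence(self):
        # from the top state, K then P ends one rung down but P then K
        # returns to the top: saturation makes the pair noncommutative
        spec = RatchetSpec(1, 1, 1, 1, 2)
        top = (2,)
        assert apply_word(top, [K(1), P(1)], spec) == (1,)
        assert apply_word(top, [P(1), K(1)], spec) == (2,)

    def test_out_of_range_action(self, ratchet22):
        with pytest.raises(ValueError):
            ratchet_apply(zero_config(ratchet22), K(3), ratchet22)

    def test_pure_k_words_commute(self, ratchet_suites):
        rng = np.random.default_rng(0)
        for suite in ratchet_suites:
            spec = suite.spec
            for word in suite.words:
                ks = tuple(a for a in word if a.kind == "K")
                perm = tuple(ks[i] for i in rng.permutation(len(ks)))
                assert apply_word(zero_config(spec), ks, spec) == apply_word(
                    zero_config(spec), perm, spec
                )

    def test_states_stay_in_range(self, ratchet_suites):
        for suite in ratchet_suites:
            spec = suite.spec
            for word in suite.words:
                cfg = apply_word(zero_config(spec), word, spec)
                assert len(cfg) == spec.n_targets
                assert all(0 <= s <= spec.T for s in cfg)


class TestConnectivityMatrix:
    def test_zero_config(self, ratchet22):
        assert connectivity_matrix(zero_config(ratchet22), ratchet22).tolist() == [
            [0, 0],
            [0, 0],
        ]

    def test_group_indicator_for_shared_targets(self):
        # with one shared target ON, every (K_i, P_j) pair wired to it
        # reports 1: the first canonical target of the (3,3,2,2) network is
        # ({1,2},{1,2}), lighting the 2x2 upper-left block
        spec = RatchetSpec(3, 3, 2, 2, 1)
        cfg = (1,) + (0,) * (spec.n_targets - 1)
        A = connectivity_matrix(cfg, spec)
        assert A.tolist() == [[1, 1, 0], [1, 1, 0], [0, 0, 0]]


class TestSequestration:
    def test_target_counts_and_order(self, seq4_reduced):
        targets = build_seq_targets(seq4_reduced)
        assert len(targets) == 7 == seq4_reduced.n_targets
        assert targets == (
            (1, 2), (1, 3), (1, 4),
            (1, 2, 3), (1, 2, 4), (1, 3, 4), (1, 2, 3, 4),
        )
        assert SeqSpec(4, reduced=False).n_targets == 15

    def test_fifteen_action_word(self, seq4_reduced):
        word = [K(2), K(4), P(2), K(3), K(2), P(4), K(1), P(3), K(4), P(1),
                K(3), P(4), K(1), P(2), P(3)]
        assert apply_word(zero_config(seq4_reduced), word, seq4_reduced) == (
            0, 0, 1, 0, 0, 0, 1,
        )

    def test_sequential_compartment_silencing(self, seq4_reduced):
        # K3 K4 K1 P3 P4: sequestering arms 3 then 4 leaves only the
        # two-arm {1,2} gene accessible to K1
        word = [K(3), K(4), K(1), P(3), P(4)]
        assert apply_word(zero_config(seq4_reduced), word, seq4_reduced) == (
            1, 0, 0, 0, 0, 0, 0,
        )

    def test_capture_is_idempotent(self, seq3_full):
        once = seq_apply(zero_config(seq3_full), K(2), seq3_full)
        assert seq_apply(once, K(2), seq3_full) == once

    def test_protection(self, seq3_full):
        # a target in state j is a fixed point of K_i and P_i for i != j
        cfg = seq_apply(zero_config(seq3_full), K(2), seq3_full)
        for a in [K(1), P(1), K(3), P(3)]:
            moved = seq_apply(cfg, a, seq3_full)
            for t, g in enumerate(build_seq_targets(seq3_full)):
                if cfg[t] == 2:
                    assert moved[t] == 2

    def test_pure_p_words_commute(self, seq_suites):
        rng = np.random.default_rng(1)
        for suite in seq_suites:
            spec = suite.spec
            for word in suite.words:
                start = apply_word(zero_config(spec), word, spec)
                ps = tuple(P(i) for i in range(1, spec.n + 1))
                perm = tuple(ps[i] for i in rng.permutation(len(ps)))
                assert apply_word(start, ps, spec) == apply_word(start, perm, spec)

    def test_capture_order_matters(self, seq3_full):
        # K1 K2 vs K2 K1 differ on any target with both arms
        a = apply_word(zero_config(seq3_full), [K(1), K(2)], seq3_full)
        b = apply_word(zero_config(seq3_full), [K(2), K(1)], seq3_full)
        assert a != b

    def test_states_stay_in_arm_sets(self, seq_suites):
        for suite in seq_suites:
            spec = suite.spec
            targets = build_seq_targets(spec)
            for word in suite.words:
                cfg = apply_word(zero_config(spec), word, spec)
                assert all(s == 0 or s in g for s, g in zip(cfg, targets))


class TestWordAlgebra:
    """Algebraic laws of the action monoids, property-tested."""

    from hypothesis import given, settings, strategies as st

    actions3 = st.tuples(st.sampled_from("KP"), st.integers(1, 3)).map(
        lambda t: __import__("noncommnet").models.Action(*t)
    )

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(actions3, max_size=8))
    def test_seq_actions_idempotent_anywhere(self, word):
        spec = SeqSpec(3, reduced=False)
        cfg = apply_word(zero_config(spec), word, spec)
        for a in spec.alphabet():
            once = apply_word(cfg, [a], spec)
            assert apply_word(once, [a], spec) == once

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(actions3, max_size=8), st.randoms(use_true_random=False))
    def test_ratchet_pure_k_suffix_commutes(self, word, rnd):
        spec = RatchetSpec(3, 3, 1, 1, 2)
        start = apply_word(zero_config(spec), word, spec)
        ks = [K(1), K(2), K(3)]
        perm = ks[:]
        rnd.shuffle(perm)
        assert apply_word(start, ks, spec) == apply_word(start, perm, spec)
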