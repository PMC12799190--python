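"""Transition counting, Chao-Shen correction, and the composed GTE pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeflow.entropy import (
    CANONICAL_CATEGORIES,
    build_transition_matrix,
    chao_shen_entropy,
    global_entropy,
    gte,
    normalize_entropy,
    row_normalize,
    stationary_distribution,
)

AB = ("a", "b")


class TestTransitionCounts:
    def test_enumerated_sequence(self):
        tc = build_transition_matrix(["b", "a", "b", "a"], labels=AB)
        assert tc.counts[1, 0] == 2  # b -> a twice
        assert tc.counts[0, 1] == 1  # a -> b once
        assert tc.counts.sum() == 3

    def test_self_transitions_counted_by_default(self):
        tc = build_transition_matrix(["a", "a", "a"], labels=AB)
        assert tc.counts[0, 0] == 2
        dropped = build_transition_matrix(["a", "a", "a"], labels=AB,
                                          drop_self_transitions=True)
        assert dropped.counts.sum() == 0

    def test_total_is_sequence_length_minus_one(self):
        seq = list(np.random.default_rng(0).choice(CANONICAL_CATEGORIES, size=500))
        tc = build_transition_matrix(seq)
        assert tc.counts.sum() == len(seq) - 1

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="mystery"):
            build_transition_matrix(["a", "mystery"], labels=AB)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(["a"], labels=AB)

    def test_frequencies_approach_generator(self):
        from gazeflow.synthetic import simulate_fixation_sequence

        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        seq = simulate_fixation_sequence(P, 10_000, 0, seed=5, labels=AB)
        tc = build_transition_matrix(seq, labels=AB)
        Phat, _ = row_normalize(tc)
        assert np.abs(Phat - P).max() < 0.03


class TestRowNormalize:
    def test_simple_row(self):
        tc = build_transition_matrix(["a", "a", "b", "a", "c"], labels=("a", "b", "c"))
        P, zero = row_normalize(tc)
        np.testing.assert_allclose(P[0], [1 / 3, 1 / 3, 1 / 3])
        assert zero[2]  # c never serves as a source (it is last)

    def test_nonzero_rows_sum_to_one(self, rng):
        seq = list(rng.choice(CANONICAL_CATEGORIES, size=300))
        P, zero = row_normalize(build_transition_matrix(seq))
        sums = P.sum(axis=1)
        np.testing.assert_allclose(sums[~zero], 1.0, atol=1e-12)
        np.testing.assert_allclose(sums[zero], 0.0)


class TestChaoShen:
    def test_point_mass_row(self):
        h, c = chao_shen_entropy([10, 0, 0])
        assert h == 0.0 and c == 1.0

    def test_hand_computed_sparse_row(self):
        # N=4, S1=2, C=0.5, p_adj=(0.25,0.125,0.125),
        # la=(1-0.75^4, 1-0.875^4, 1-0.875^4) -> 2.5438 bits
        h, c = chao_shen_entropy([2, 1, 1])
        assert c == 0.5
        expected = 0.5 / (1 - 0.75**4) + 2 * (0.375 / (1 - 0.875**4))
        assert h == pytest.approx(expected, abs=1e-12)
        assert h == pytest.approx(2.544, abs=1e-3)

    def test_large_sample_uniform_limit(self, rng):
        counts = rng.multinomial(50_000, np.full(8, 1 / 8))
        h, c = chao_shen_entropy(counts)
        assert h == pytest.approx(3.0, abs=0.02)
        assert c > 0.999

    def test_all_singletons_degenerate_coverage(self):
        h, c = chao_shen_entropy([1, 1, 1, 1])
        assert c == pytest.approx(0.25)
        assert np.isfinite(h) and h > 0

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            chao_shen_entropy([0, 0, 0])

    def test_matches_plugin_when_no_singletons(self, rng):
        # coverage is 1 and inclusion probabilities ~1 at large counts
        counts = np.array([4000, 3000, 2000, 1000])
        h, _ = chao_shen_entropy(counts)
        p = counts / counts.sum()
        assert h == pytest.approx(-np.sum(p * np.log2(p)), abs=1e-6)


class TestStationary:
    def test_uniform_matrix_gives_uniform_pi(self):
        P = np.full((8, 8), 1 / 8)
        pi, method = stationary_distribution(P, np.full(8, 10.0))
        np.testing.assert_allclose(pi, 1 / 8, atol=1e-12)
        assert method == "eigen"

    def test_two_state_solved_by_hand(self):
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        pi, method = stationary_distribution(P, np.array([5.0, 5.0]))
        np.testing.assert_allclose(pi, [5 / 6, 1 / 6], atol=1e-12)
        assert method == "eigen"

    def test_reducible_blocks_fall_back_to_empirical(self):
        P = np.zeros((4, 4))
        P[0, 0] = P[1, 1] = P[2, 2] = P[3, 3] = 1.0  # four absorbing states
        pi, method = stationary_distribution(P, np.array([4.0, 4.0, 1.0, 1.0]))
        assert method == "empirical"
        np.testing.assert_allclose(pi, [0.4, 0.4, 0.1, 0.1])

    def test_unobserved_rows_get_zero_weight(self):
        P = np.zeros((3, 3))
        P[0, :2] = [0.5, 0.5]
        P[1, :2] = [0.5, 0.5]
        pi, _ = stationary_distribution(P, np.array([3.0, 3.0, 0.0]))
        assert pi[2] == 0.0
        assert pi.sum() == pytest.approx(1.0)


class TestGlobalAndNormalize:
    def test_weighted_average(self):
        assert global_entropy(np.array([2.0, 0.0]), np.array([0.5, 0.5])) == 1.0
        assert global_entropy(np.full(4, 3.0), np.full(4, 0.25)) == pytest.approx(3.0)

    def test_point_mass_weight_selects_row(self):
        H = np.array([1.2, 2.7, 0.3])
        pi = np.array([0.0, 1.0, 0.0])
        assert global_entropy(H, pi) == pytest.approx(2.7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            global_entropy(np.ones(3), np.ones(2) / 2)

    @pytest.mark.parametrize("h, k, expected", [(3.0, 8, 1.0), (0.0, 8, 0.0), (1.5, 8, 0.5)])
    def test_normalization(self, h, k, expected):
        assert normalize_entropy(h, k) == pytest.approx(expected)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            normalize_entropy(1.0, 1)


class TestGTE:
    def test_deterministic_cycle_is_zero(self):
        seq = ["a", "b"] * 500
        assert gte(seq, labels=AB).H_norm == 0.0

    def test_uniform_chain_approaches_one(self, rng):
        seq = list(rng.choice(CANONICAL_CATEGORIES, size=50_000))
        assert gte(seq).H_norm >= 0.98

    def test_empirical_stationary_option(self, rng):
        seq = list(rng.choice(CANONICAL_CATEGORIES[:4], size=2_000))
        res = gte(seq, stationary="empirical")
        assert res.pi_method == "empirical"
        assert 0.0 <= res.H_norm <= 1.0

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.sampled_from(CANONICAL_CATEGORIES), min_size=2, max_size=400))
    def test_bounded_for_any_sequence(self, seq):
        res = gte(seq)
        assert 0.0 <= res.H_norm <= 1.0
        assert res.pi.sum() == pytest.approx(1.0)
        assert (res.pi >= 0).all()

    def test_label_permutation_invariance(self, rng):
        seq = list(rng.choice(CANONICAL_CATEGORIES, size=3_000,
                              p=[0.3, 0.25, 0.15, 0.1, 0.08, 0.05, 0.04, 0.03]))
        base = gte(seq)
        perm = list(rng.permutation(CANONICAL_CATEGORIES))
        mapping = dict(zip(CANONICAL_CATEGORIES, perm))
        res = gte([mapping[s] for s in seq])
        assert res.H_global == pytest.approx(base.H_global, rel=1e-9)
        assert res.H_norm == pytest.approx(base.H_norm, rel=1e-9)

    def test_shuffling_structured_sequence_raises_entropy(self, rng):
        # block-structured sequence with uniform marginals but concentrated rows
        seq = [CANONICAL_CATEGORIES[i] for i in range(8) for _ in range(400)]
        structured = gte(seq).H_norm
        shuffled = list(seq)
        rng.shuffle(shuffled)
        assert gte(shuffled).H_norm > structured
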