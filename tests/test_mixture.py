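import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rxseq import (
    MixtureMarkovParams,
    component_log_likelihood,
    e_step,
    fit_em,
    load_model,
    m_step,
    match_components,
    mixture_log_likelihood,
    posterior_assign,
    save_model,
)
from conftest import random_dataset, random_params


def naive_mixture_ll(seqs, params):
    """Brute-force oracle: plain products, no log-space tricks."""
    total = 0.0
    for s in seqs:
        p = 0.0
        for k in range(params.K):
            pk = params.initial[k, s[0]]
            for a, b in zip(s, s[1:]):
                pk *= params.transition[k, a, b]
            p += params.mixing[k] * pk
        total += math.log(p)
    return total


def uniform_params(K, S):
    return MixtureMarkovParams(
        mixing=np.full(K, 1.0 / K),
        initial=np.full((K, S), 1.0 / S),
        transition=np.full((K, S, S), 1.0 / S),
    )


class TestComponentLogLikelihood:
    def test_uniform_chain(self):
        params = uniform_params(1, 5)
        ll = component_log_likelihood([2, 0, 4], 0, params)
        assert ll == pytest.approx(3 * math.log(1 / 5), abs=1e-12)

    def test_probability_one_path(self):
        params = MixtureMarkovParams(
            mixing=np.array([1.0]),
            initial=np.array([[1.0, 0.0]]),
            transition=np.array([[[0.0, 1.0], [1.0, 0.0]]]),
        )
        assert component_log_likelihood([0, 1, 0], 0, params) == 0.0

    def test_hand_multiplication(self, two_state_params):
        ll = component_log_likelihood([0, 0, 1], 0, two_state_params)
        assert ll == pytest.approx(math.log(0.5 * 0.9 * 0.1), abs=1e-12)

    def test_zero_probability_is_neg_inf(self):
        params = MixtureMarkovParams(
            mixing=np.array([1.0]),
            initial=np.array([[1.0, 0.0]]),
            transition=np.array([[[1.0, 0.0], [0.5, 0.5]]]),
        )
        assert component_log_likelihood([0, 1], 0, params) == -np.inf

    def test_state_out_of_range(self, two_state_params):
        with pytest.raises(ValueError):
            component_log_likelihood([0, 7], 0, two_state_params)


class TestMixtureLogLikelihood:
    def test_degenerate_mixing(self, two_state_params):
        p = MixtureMarkovParams(
            mixing=np.array([1.0, 0.0]),
            initial=two_state_params.initial,
            transition=two_state_params.transition,
        )
        seqs = [[0, 1, 1], [1, 0], [0]]
        expected = sum(component_log_likelihood(s, 0, p) for s in seqs)
        assert mixture_log_likelihood(seqs, p) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            K = int(rng.integers(1, 4))
            S = int(rng.integers(2, 6))
            n = int(rng.integers(1, 21))
            seqs, params = random_dataset(rng, n, K, S, max_len=6)
            assert mixture_log_likelihood(seqs, params) == pytest.approx(
                naive_mixture_ll(seqs, params), abs=1e-10
            )

    def test_duplication_doubles(self, two_state_params):
        seqs = [[0, 1, 1], [1, 0, 0, 1]]
        ll = mixture_log_likelihood(seqs, two_state_params)
        assert mixture_log_likelihood(seqs + seqs, two_state_params) == pytest.approx(
            2 * ll, abs=1e-12
        )

    def test_empty_is_zero(self, two_state_params):
        assert mixture_log_likelihood([], two_state_params) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        seqs, params = random_dataset(rng, 8, 3, 4, max_len=5)
        perm = rng.permutation(3)
        assert mixture_log_likelihood(seqs, params.permuted(perm)) == pytest.approx(
            mixture_log_likelihood(seqs, params), abs=1e-10
        )


class TestEStep:
    def test_identical_components(self):
        params = uniform_params(2, 3)
        gamma = e_step([[0, 1], [2, 2, 1]], params)
        assert np.allclose(gamma, 0.5, atol=1e-12)

    def test_degenerate_mixing(self, two_state_params):
        p = MixtureMarkovParams(
            mixing=np.array([1.0, 0.0]),
            initial=two_state_params.initial,
            transition=two_state_params.transition,
        )
        gamma = e_step([[0, 1], [1, 1, 0]], p)
        assert np.allclose(gamma, [[1, 0], [1, 0]], atol=1e-15)

    def test_hand_posterior(self, two_state_params):
        # L0 = 0.5*0.9*0.1 = 0.045 ; L1 = 0.5*0.8*0.2 = 0.080
        gamma = e_step([[0, 0, 1]], two_state_params)
        expected = np.array([0.045, 0.080]) / 0.125
        assert np.allclose(gamma[0], expected, atol=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs, params = random_dataset(rng, 30, 3, 5, max_len=8)
        gamma = e_step(seqs, params)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_inexplicable_sequence_errors(self):
        params = MixtureMarkovParams(
            mixing=np.array([1.0]),
            initial=np.array([[1.0, 0.0]]),
            transition=np.array([[[1.0, 0.0], [0.5, 0.5]]]),
        )
        with pytest.raises(ValueError, match="zero likelihood"):
            e_step([[0, 1]], params)


class TestMStep:
    def test_k1_closed_form(self):
        seqs = [[0, 1, 1, 0], [1, 1], [0, 0, 1]]
        params = m_step(seqs, np.ones((3, 1)), pseudocount=0.0, S=2)
        # initial: first states 0,1,0
        assert np.allclose(params.initial[0], [2 / 3, 1 / 3])
        # pooled transitions: 0->1 x2, 1->1 x2, 1->0 x1, 0->0 x1
        assert np.allclose(params.transition[0], [[1 / 3, 2 / 3], [1 / 3, 2 / 3]])

    def test_one_hot_equals_per_group_closed_form(self):
        rng = np.random.default_rng(5)
        seqs_a, _ = random_dataset(rng, 12, 1, 3, max_len=6)
        seqs_b, _ = random_dataset(rng, 9, 1, 3, max_len=6)
        onehot = np.zeros((21, 2))
        onehot[:12, 0] = 1.0
        onehot[12:, 1] = 1.0
        both = m_step(seqs_a + seqs_b, onehot, pseudocount=0.0, S=3)
        only_a = m_step(seqs_a, np.ones((12, 1)), pseudocount=0.0, S=3)
        only_b = m_step(seqs_b, np.ones((9, 1)), pseudocount=0.0, S=3)
        assert np.allclose(both.transition[0], only_a.transition[0], atol=1e-12)
        assert np.allclose(both.transition[1], only_b.transition[0], atol=1e-12)
        assert np.allclose(both.mixing, [12 / 21, 9 / 21], atol=1e-12)

    def test_large_pseudocount_flattens(self):
        seqs = [[0, 1, 0, 1, 0]]
        params = m_step(seqs, np.ones((1, 1)), pseudocount=1e9, S=2)
        assert np.allclose(params.transition[0], 0.5, atol=1e-6)

    def test_unvisited_state_row_uniform(self):
        params = m_step([[0, 0, 0]], np.ones((1, 1)), pseudocount=0.0, S=3)
        assert np.allclose(params.transition[0, 1], 1 / 3)
        assert np.allclose(params.transition[0, 2], 1 / 3)


class TestFitEM:
    def test_k1_equals_closed_form(self):
        rng = np.random.default_rng(17)
        seqs, _ = random_dataset(rng, 40, 1, 5, max_len=8)
        fit = fit_em(seqs, K=1, n_restarts=1, pseudocount=0.0, seed=0)
        closed = m_step(seqs, np.ones((40, 1)), pseudocount=0.0, S=5)
        assert np.allclose(fit.params.initial, closed.initial, atol=1e-10)
        assert np.allclose(fit.params.transition, closed.transition, atol=1e-10)
        assert len(fit.ll_trace) <= 2
        assert fit.converged

    def test_determinism(self):
        rng = np.random.default_rng(23)
        seqs, _ = random_dataset(rng, 60, 2, 5, max_len=10)
        a = fit_em(seqs, K=2, n_restarts=3, seed=99)
        b = fit_em(seqs, K=2, n_restarts=3, seed=99)
        assert a.log_likelihood == b.log_likelihood
        assert a.ll_trace == b.ll_trace
        assert np.array_equal(a.params.transition, b.params.transition)

    def test_trace_monotone_and_final(self):
        rng = np.random.default_rng(31)
        seqs, _ = random_dataset(rng, 80, 3, 5, max_len=12)
        fit = fit_em(seqs, K=3, n_restarts=4, seed=7)
        trace = np.array(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert fit.log_likelihood == trace[-1]

    def test_mle_dominates_truth(self, paper_cohort, paper_sequences):
        cfg, _ = paper_cohort
        sequences, _ = paper_sequences
        fit = fit_em(sequences, K=4, n_restarts=5, seed=3)
        ll_truth = mixture_log_likelihood(sequences, cfg.params)
        assert ll_truth <= fit.log_likelihood + 1e-6 * abs(fit.log_likelihood)

    def test_k_exceeds_n_warns(self):
        with pytest.warns(UserWarning):
            fit_em([[0, 1]], K=3, n_restarts=1, seed=0)


class TestPosteriorAssign:
    def test_all_to_component_zero(self):
        rng = np.random.default_rng(3)
        seqs, params = random_dataset(rng, 10, 1, 4, max_len=5)
        p = MixtureMarkovParams(
            mixing=np.array([1.0, 0.0, 0.0]),
            initial=np.tile(params.initial, (3, 1)),
            transition=np.tile(params.transition, (3, 1, 1)),
        )
        assert all(a.cluster == 0 for a in posterior_assign(seqs, p))

    def test_tie_breaks_low_index(self):
        params = uniform_params(2, 3)
        assignments = posterior_assign([[0, 1, 2]], params)
        assert assignments[0].cluster == 0
        assert np.allclose(assignments[0].posterior, 0.5)

    def test_identical_sequences_identical_assignments(self):
        rng = np.random.default_rng(8)
        _, params = random_dataset(rng, 2, 2, 3, max_len=4)
        out = posterior_assign([[0, 1], [0, 1]], params)
        assert out[0].cluster == out[1].cluster
        assert np.array_equal(out[0].posterior, out[1].posterior)


class TestMatchComponents:
    def test_identity(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, 4, 5)
        assert match_components(p, p) == (0, 1, 2, 3)

    def test_swap(self):
        rng = np.random.default_rng(2)
        p = random_params(rng, 3, 4)
        swapped = p.permuted([2, 0, 1])
        # estimated[perm[k]] must match truth[k]
        perm = match_components(swapped, p)
        for k in range(3):
            assert np.allclose(swapped.transition[perm[k]], p.transition[k])

    def test_noise_robust(self):
        rng = np.random.default_rng(3)
        p = random_params(rng, 4, 5)
        noisy_t = p.transition + rng.uniform(0, 0.01, p.transition.shape)
        noisy_t /= noisy_t.sum(axis=2, keepdims=True)
        noisy = MixtureMarkovParams(p.mixing, p.initial, noisy_t)
        assert match_components(noisy, p) == (0, 1, 2, 3)

    def test_k_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            match_components(random_params(rng, 2, 3), random_params(rng, 3, 3))


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    seqs, _ = random_dataset(rng, 30, 2, 5, max_len=6)
    fit = fit_em(seqs, K=2, n_restarts=2, seed=5)
    path = tmp_path / "model.json"
    save_model(fit, path)
    back = load_model(path)
    assert np.array_equal(back.params.mixing, fit.params.mixing)
    assert np.array_equal(back.params.initial, fit.params.initial)
    assert np.array_equal(back.params.transition, fit.params.transition)
    assert back.log_likelihood == fit.log_likelihood
    assert back.seed == fit.seed
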