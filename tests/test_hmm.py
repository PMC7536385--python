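"""HMM inference against brute-force oracles, plus recovery and selection."""

import numpy as np
import pytest

from brainstates.dataio import concatenate
from brainstates.hmm import (
    HMMParams,
    aic,
    align_states,
    decode,
    fit_hmm,
    forward_backward,
    n_free_params,
    permute_params,
    relabel_path,
    select_states,
    viterbi,
)
from brainstates.simulate import sample_hmm_dataset, state_mean_patterns

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm_params


class TestForwardBackward:
    def test_single_state_posteriors_and_loglik(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        params = HMMParams(
            np.array([1.0]), np.array([[1.0]]),
            X.mean(axis=0, keepdims=True), np.array([np.eye(3)]),
        )
        gamma, ll = forward_backward(params, X)
        assert np.all(gamma == 1.0)
        from scipy.stats import multivariate_normal

        direct = sum(
            multivariate_normal.logpdf(x, params.state_means[0], np.eye(3))
            for x in X
        )
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_matches_path_enumeration_small(self):
        pi = np.array([0.7, 0.3])
        A = np.array([[0.8, 0.2], [0.4, 0.6]])
        means = np.array([[-1.0], [1.0]])
        covs = np.array([[[0.5]], [[0.8]]])
        params = HMMParams(pi, A, means, covs)
        X = np.array([[0.2], [-0.4]])
        _, ll = forward_backward(params, X)
        assert ll == pytest.approx(brute_force_loglik(params, X), abs=1e-10)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = random_hmm_params(4, 3, rng)
        X = rng.normal(size=(50, 3))
        gamma, _ = forward_backward(params, X)
        assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-8

    def test_matches_hmmlearn_loglik(self):
        """Independent library cross-check of the forward pass."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(2)
        params = random_hmm_params(3, 4, rng)
        X = rng.normal(size=(80, 4))
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                     init_params="")
        model.startprob_ = params.initial_probs
        model.transmat_ = params.transition_matrix
        model.means_ = params.state_means
        model.covars_ = params.state_covariances
        _, ll = forward_backward(params, X)
        assert ll == pytest.approx(model.score(X), abs=1e-6)


class TestViterbi:
    def test_tie_break_to_lowest_state(self):
        K = 3
        means = np.zeros((K, 2))
        covs = np.array([np.eye(2)] * K)
        params = HMMParams(np.full(K, 1 / K), np.full((K, K), 1 / K),
                           means, covs)
        X = np.random.default_rng(3).normal(size=(6, 2))
        assert np.all(viterbi(params, X) == 1)

    def test_enumeration_oracle_small_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 6))
            D = int(rng.integers(1, 3))
            params = random_hmm_params(K, D, rng)
            X = rng.normal(size=(T, D))
            assert np.array_equal(
                viterbi(params, X), brute_force_viterbi(params, X)
            )


class TestAic:
    def test_closed_form_minimal(self):
        assert n_free_params(1, 1) == 2
        assert aic(0.0, 1, 1) == 4.0

    def test_study_scale_dimensions(self):
        assert n_free_params(10, 14) == 140 + 1050 + 90 + 9
        assert aic(-10000.0, 10, 14) == pytest.approx(22578.0)

    def test_penalty_monotone_in_K(self):
        lls = aic(-500.0, 3, 5), aic(-500.0, 4, 5), aic(-500.0, 6, 5)
        assert lls[0] < lls[1] < lls[2]


class TestFit:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=2.0, size=(200, 3))
        fit = fit_hmm(X, K=1, restarts=1, max_iter=10, seed=0)
        assert np.allclose(fit.params.state_means[0], X.mean(axis=0),
                           atol=1e-8)
        assert fit.params.transition_matrix[0, 0] == pytest.approx(1.0)

    def test_alternating_clusters_high_switching(self):
        rng = np.random.default_rng(6)
        T = 400
        labels = np.arange(T) % 2
        X = np.where(labels[:, None] == 0, -4.0, 4.0) + rng.normal(
            scale=0.3, size=(T, 2)
        )
        fit = fit_hmm(X, K=2, restarts=3, max_iter=100, seed=1)
        A = fit.params.transition_matrix
        assert A[0, 1] > 0.95 and A[1, 0] > 0.95

    def test_final_loglik_matches_forward_pass(self, recovery_problem,
                                               recovery_fit):
        _, data, _ = recovery_problem
        total = sum(
            forward_backward(recovery_fit.params, data.segment_values(s))[1]
            for s in data.segments
        )
        assert recovery_fit.loglik == pytest.approx(total, abs=1e-6)

    def test_loglik_trace_monotone(self, recovery_fit):
        tr = recovery_fit.loglik_trace
        assert np.all(np.diff(tr) >= -1e-6 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_rejects_undersized_data(self):
        X = np.random.default_rng(7).normal(size=(10, 4))
        with pytest.raises(ValueError, match="too few rows"):
            fit_hmm(X, K=3)

    def test_label_permutation_invariance(self):
        """Permuting generator state labels permutes the fit identically."""
        K, D = 3, 4
        means = state_mean_patterns(K, D, 2.5)
        A = np.array([[0.8, 0.15, 0.05],
                      [0.1, 0.8, 0.1],
                      [0.05, 0.15, 0.8]])
        params = HMMParams(np.full(K, 1 / K), A, means,
                           np.array([np.eye(D)] * K))
        perm = np.array([2, 0, 1])
        permuted = permute_params(params, perm)
        data, _ = sample_hmm_dataset(params, 4, 300, seed=8)
        fit_a = fit_hmm(data, K=K, restarts=2, max_iter=100, seed=2)
        pa = align_states(params, fit_a.params)
        pb = align_states(permuted, fit_a.params)
        aligned_a = permute_params(fit_a.params, pa)
        aligned_b = permute_params(fit_a.params, pb)
        assert np.allclose(aligned_a.state_means[perm],
                           aligned_b.state_means)


class TestRecovery:
    def test_parameter_recovery(self, recovery_problem, recovery_fit):
        params, data, paths = recovery_problem
        perm = align_states(params, recovery_fit.params)
        aligned = permute_params(recovery_fit.params, perm)
        assert np.abs(
            aligned.transition_matrix - params.transition_matrix
        ).max() < 0.05
        for k in range(params.K):
            r = np.corrcoef(params.state_means[k], aligned.state_means[k])[0, 1]
            assert r > 0.99
        dec = decode(aligned, data)
        acc = np.mean([np.mean(p == g) for p, g in zip(dec.paths, paths)])
        assert acc > 0.95


class TestAlignStates:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(9)
        params = random_hmm_params(4, 5, rng)
        assert np.array_equal(align_states(params, params), np.arange(4))
        rev = permute_params(params, np.array([3, 2, 1, 0]))
        assert np.array_equal(align_states(params, rev),
                              np.array([3, 2, 1, 0]))

    def test_relabel_path_round_trip(self):
        rng = np.random.default_rng(10)
        params = random_hmm_params(3, 4, rng)
        perm = np.array([1, 2, 0])
        shuffled = permute_params(params, perm)   # shuffled state i = perm[i]
        path = rng.integers(1, 4, size=20)        # in `params` labels
        inverse = np.argsort(perm)
        shuffled_path = inverse[path - 1] + 1     # same states, new labels
        # relabelling through the alignment recovers the reference labels
        back = relabel_path(shuffled_path, align_states(params, shuffled))
        assert np.array_equal(back, path)

    def test_k_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            align_states(random_hmm_params(3, 4, rng),
                         random_hmm_params(4, 4, rng))


class TestSelectStates:
    def test_single_candidate_recommended(self):
        X = np.random.default_rng(12).normal(size=(300, 3))
        sel = select_states(X, [2], restarts=1, max_iter=30, seed=0)
        assert sel.recommended_K == 2
        assert len(sel.rows) == 1

    def test_surplus_states_underoccupied(self):
        K, D = 2, 4
        means = state_mean_patterns(K, D, 3.0)
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        params = HMMParams(np.full(K, 0.5), A, means,
                           np.array([np.eye(D)] * K))
        data, _ = sample_hmm_dataset(params, 3, 250, seed=13)
        sel = select_states(data, [2, 5], restarts=2, max_iter=100, seed=3)
        row5 = [r for r in sel.rows if r.K == 5][0]
        row2 = [r for r in sel.rows if r.K == 2][0]
        assert row5.min_fo < row2.min_fo

    def test_empty_k_list_rejected(self):
        with pytest.raises(ValueError):
            select_states(np.zeros((50, 2)), [], seed=0)
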