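"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from brainstates.dataio import concatenate
from brainstates.hmm import HMMParams, fit_hmm
from brainstates.simulate import (
    SimConfig,
    generate_cohort,
    sample_hmm_dataset,
    state_mean_patterns,
)


def brute_force_loglik(params: HMMParams, X: np.ndarray) -> float:
    """Log-likelihood by explicit summation over all K^T state paths."""
    K, T = params.K, len(X)
    dens = np.array(
        [
            [
                multivariate_normal.pdf(
                    x, params.state_means[k], params.state_covariances[k]
                )
                for k in range(K)
            ]
            for x in X
        ]
    )
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = params.initial_probs[path[0]] * dens[0, path[0]]
        for t in range(1, T):
            p *= params.transition_matrix[path[t - 1], path[t]] * dens[t, path[t]]
        total += p
    return float(np.log(total))


def brute_force_viterbi(params: HMMParams, X: np.ndarray) -> np.ndarray:
    """Best path by exhaustive enumeration; ties break to the lowest path."""
    K, T = params.K, len(X)
    logdens = np.array(
        [
            [
                multivariate_normal.logpdf(
                    x, params.state_means[k], params.state_covariances[k]
                )
                for k in range(K)
            ]
            for x in X
        ]
    )
    with np.errstate(divide="ignore"):
        logpi = np.log(params.initial_probs)
        logA = np.log(params.transition_matrix)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logdens[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logdens[t, path[t]]
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path) + 1


def random_hmm_params(K: int, D: int, rng: np.random.Generator) -> HMMParams:
    """A random valid parameter set with well-conditioned covariances."""
    pi = rng.dirichlet(np.ones(K) * 5)
    A = rng.dirichlet(np.ones(K) * 5, size=K)
    means = rng.normal(scale=2.0, size=(K, D))
    covs = np.empty((K, D, D))
    for k in range(K):
        W = rng.normal(size=(D, D)) * 0.3
        covs[k] = W @ W.T + np.eye(D)
    return HMMParams(pi, A, means, covs)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-session cohort reused across module tests."""
    cfg = SimConfig(
        n_subjects=5, n_sessions=2, K_true=4, D=6,
        T_rest=80, T_movie=120, seed=42,
    )
    runs, truth = generate_cohort(cfg)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def recovery_problem():
    """Ground-truth HMM + sampled dataset for fit/decoding recovery tests."""
    K, D = 4, 6
    means = state_mean_patterns(K, D, 2.0)
    A = np.full((K, K), 0.1 / (K - 1))
    np.fill_diagonal(A, 0.9)
    params = HMMParams(
        np.full(K, 1.0 / K), A, means, np.array([np.eye(D)] * K)
    )
    data, paths = sample_hmm_dataset(params, 14, 750, seed=5)
    return params, data, paths


@pytest.fixture(scope="session")
def recovery_fit(recovery_problem):
    """The (expensive) EM fit of the recovery problem, shared across tests."""
    _, data, _ = recovery_problem
    return fit_hmm(data, K=4, restarts=3, max_iter=200, seed=1)
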