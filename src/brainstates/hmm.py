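"""Gaussian-emission hidden Markov model on concatenated multi-run data.

Each hidden brain state is a multivariate Gaussian over the D network
channels (full covariance).  Fitting is maximum-likelihood EM (Baum-Welch)
with multiple seeded restarts; inference is segment-aware: probability never
flows across run boundaries and every segment re-uses the shared
initial-state distribution.  Model order is chosen by AIC among models whose
every state remains occupied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .dataio import ConcatDataset, Segment

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """State means/covariances plus initial and transition probabilities."""

    initial_probs: np.ndarray          # (K,)
    transition_matrix: np.ndarray      # (K, K) row-stochastic
    state_means: np.ndarray            # (K, D)
    state_covariances: np.ndarray      # (K, D, D) SPD

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        K = self.K
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(self.initial_probs.sum(), 1.0, atol=1e-8):
            raise ValueError("initial probabilities must sum to 1")
        if self.state_covariances.shape != (K, self.D, self.D):
            raise ValueError("covariance stack shape mismatch")

    @property
    def K(self) -> int:
        return self.state_means.shape[0]

    @property
    def D(self) -> int:
        return self.state_means.shape[1]

    def to_dict(self) -> dict:
        return {
            "schema": "brainstates.hmm_params.v1",
            "K": self.K,
            "D": self.D,
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "state_means": self.state_means.tolist(),
            "state_covariances": self.state_covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            initial_probs=np.array(d["initial_probs"]),
            transition_matrix=np.array(d["transition_matrix"]),
            state_means=np.array(d["state_means"]),
            state_covariances=np.array(d["state_covariances"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HMMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitResult:
    params: HMMParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    restart_index: int
    seed: int
    n_free_params: int
    aic: float

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class StateDecoding:
    """Viterbi paths (1-based state labels) and posteriors, per segment."""

    segments: list[Segment]
    paths: list[np.ndarray]
    posteriors: list[np.ndarray]

    def path_for(self, subject_id: str, session: str, condition: str) -> np.ndarray:
        for seg, path in zip(self.segments, self.paths):
            if (seg.subject_id, seg.session, seg.condition) == (
                subject_id, session, condition
            ):
                return path
        raise KeyError((subject_id, session, condition))


def n_free_params(K: int, D: int) -> int:
    """Free parameters: means + covariances + transitions + initial probs."""
    return K * D + K * D * (D + 1) // 2 + K * (K - 1) + (K - 1)


def aic(loglik: float, K: int, D: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    return 2.0 * n_free_params(K, D) - 2.0 * loglik


def _log_emissions(params: HMMParams, X: np.ndarray) -> np.ndarray:
    """Per-state Gaussian log-densities, shape (T, K)."""
    T = X.shape[0]
    out = np.empty((T, params.K))
    for k in range(params.K):
        cov = params.state_covariances[k]
        chol = np.linalg.cholesky(cov)
        diff = X - params.state_means[k]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (params.D * _LOG2PI + logdet + maha)
    return out


def _forward_backward_batch(
    pi: np.ndarray, A: np.ndarray, logB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length segments.

    ``logB`` has shape (S, T, K).  Returns (gamma (S,T,K), xi_sum (K,K)
    summed over the whole batch, first_gamma (K,) summed over segments,
    loglik (S,)).  Emission log-densities are shifted per timepoint before
    exponentiation so the scaled recursion cannot underflow for any one
    dominant state.
    """
    S, T, K = logB.shape
    shift = logB.max(axis=2)
    B = np.exp(logB - shift[..., None])

    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = pi * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0.0) or not np.all(np.isfinite(c[:, 0])):
        raise FloatingPointError(
            "zero total likelihood at t=0; emission densities underflowed — "
            "consider a larger covariance ridge"
        )
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        ct = a.sum(axis=1)
        if np.any(ct <= 0.0) or not np.all(np.isfinite(ct)):
            raise FloatingPointError(
                f"zero total likelihood at t={t}; emission densities "
                "underflowed — consider a larger covariance ridge"
            )
        c[:, t] = ct
        alpha[:, t] = a / ct[:, None]

    gamma = np.empty((S, T, K))
    beta = np.ones((S, K))
    gamma[:, T - 1] = alpha[:, T - 1]
    M = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        nb = (B[:, t + 1] * beta) / c[:, t + 1, None]
        M += alpha[:, t].T @ nb
        beta = nb @ A.T
        g = alpha[:, t] * beta
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    xi_sum = A * M
    loglik = np.sum(np.log(c), axis=1) + np.sum(shift, axis=1)
    return gamma, xi_sum, gamma[:, 0].sum(axis=0), loglik


def forward_backward(
    params: HMMParams, segment: np.ndarray
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and log-likelihood for one segment."""
    X = np.atleast_2d(np.asarray(segment, dtype=float))
    logB = _log_emissions(params, X)
    gamma, _, _, ll = _forward_backward_batch(
        params.initial_probs, params.transition_matrix, logB[None]
    )
    return gamma[0], float(ll[0])


def viterbi(params: HMMParams, segment: np.ndarray) -> np.ndarray:
    """Most probable state path (1-based); ties break to the lowest index."""
    X = np.atleast_2d(np.asarray(segment, dtype=float))
    logB = _log_emissions(params, X)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(params.initial_probs)
        logA = np.log(params.transition_matrix)
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        # np.argmax returns the first (lowest) index on ties
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path + 1


def _ridge(cov: np.ndarray) -> np.ndarray:
    """Covariance regularization: delta*I with delta = 1e-6 tr(S)/D."""
    D = cov.shape[0]
    delta = 1e-6 * np.trace(cov) / D
    if delta <= 0 or not np.isfinite(delta):
        delta = 1e-8
    return cov + delta * np.eye(D)


def _init_params(
    X: np.ndarray, K: int, rng: np.random.Generator
) -> HMMParams:
    """K-means-style means on a seeded subsample; a single pooled
    within-cluster covariance shared by all states; sticky transitions
    (0.9 self).

    Pooling (rather than the raw global covariance) matters when the
    between-state spread dominates the within-state noise: a global
    covariance makes the initial emission densities so flat that EM can
    collapse all states onto the grand mean.
    """
    N, D = X.shape
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
        covs = _ridge(np.cov(X.T, ddof=0).reshape(D, D))[None]
    else:
        from sklearn.cluster import KMeans

        n_sub = min(N, 2000)
        idx = rng.choice(N, size=n_sub, replace=False)
        km = KMeans(
            n_clusters=K, n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X[idx])
        means = km.cluster_centers_
        resid = X[idx] - means[km.labels_]
        pooled = _ridge(np.cov(resid.T, ddof=0).reshape(D, D))
        covs = np.repeat(pooled[None], K, axis=0)
    if K == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(A, 0.9)
    pi = np.full(K, 1.0 / K)
    return HMMParams(pi, A, means, covs)


def _as_segment_arrays(data) -> tuple[list[np.ndarray], list[Segment] | None]:
    if isinstance(data, ConcatDataset):
        return [data.segment_values(s) for s in data.segments], data.segments
    X = np.atleast_2d(np.asarray(data, dtype=float))
    return [X], None


def _em_single(
    segs: list[np.ndarray], K: int, max_iter: int, tol: float,
    rng: np.random.Generator,
) -> tuple[HMMParams, list[float], bool, int]:
    X = np.vstack(segs)
    N, D = X.shape
    # group equal-length segments so forward-backward runs batched
    offsets = np.cumsum([0] + [len(s) for s in segs])
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(segs):
        groups.setdefault(len(s), []).append(i)
    group_idx = {
        T: np.array([np.arange(offsets[i], offsets[i] + T) for i in members])
        for T, members in groups.items()
    }
    params = _init_params(X, K, rng)
    trace: list[float] = []
    converged = False

    def e_step(p: HMMParams):
        logB_all = _log_emissions(p, X)
        G_all = np.empty((N, K))
        xi_total = np.zeros((K, K))
        first_total = np.zeros(K)
        ll = 0.0
        for T, idx in group_idx.items():
            gamma, xi_sum, first, seg_ll = _forward_backward_batch(
                p.initial_probs, p.transition_matrix, logB_all[idx]
            )
            G_all[idx.ravel()] = gamma.reshape(-1, K)
            xi_total += xi_sum
            first_total += first
            ll += float(seg_ll.sum())
        return G_all, xi_total, first_total, ll

    for it in range(max_iter):
        G_all, xi_total, first_total, ll = e_step(params)
        trace.append(ll)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if rel < tol:
                converged = True
                break
        # M-step
        G = G_all
        weights = G.sum(axis=0)
        weights = np.maximum(weights, 1e-12)
        means = (G.T @ X) / weights[:, None]
        covs = np.empty((K, D, D))
        for k in range(K):
            diff = X - means[k]
            covs[k] = _ridge((diff.T * G[:, k]) @ diff / weights[k])
        pi = first_total / first_total.sum()
        if K == 1:
            A = np.ones((1, 1))
        else:
            rows = xi_total.sum(axis=1, keepdims=True)
            A = np.where(rows > 1e-12, xi_total / np.maximum(rows, 1e-12),
                         1.0 / K)
            A /= A.sum(axis=1, keepdims=True)
        params = HMMParams(pi, A, means, covs)
    return params, trace, converged, len(trace)


def fit_hmm(
    data: ConcatDataset | np.ndarray,
    K: int,
    restarts: int = 15,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FitResult:
    """Fit a K-state Gaussian HMM by EM with seeded restarts.

    The restart with the highest final log-likelihood wins.  Probability
    never flows across segment boundaries; all segments share the initial
    distribution.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    segs, _ = _as_segment_arrays(data)
    X = np.vstack(segs)
    N, D = X.shape
    if N < K * (D + 2):
        raise ValueError(f"too few rows ({N}) to fit K={K} states in D={D}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contain non-finite values")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(restarts)
    best: FitResult | None = None
    failures: list[str] = []
    for r in range(restarts):
        rng = np.random.default_rng(children[r])
        try:
            params, trace, conv, n_iter = _em_single(segs, K, max_iter, tol, rng)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append(f"restart {r}: {exc}")
            continue
        res = FitResult(
            params=params,
            loglik_trace=np.array(trace),
            converged=conv,
            n_iter=n_iter,
            restart_index=r,
            seed=seed,
            n_free_params=n_free_params(K, D),
            aic=aic(trace[-1], K, D),
        )
        if best is None or res.loglik > best.loglik:
            best = res
    if best is None:
        raise RuntimeError(
            "all EM restarts failed:\n" + "\n".join(failures)
        )
    return best


def decode(params: HMMParams, data: ConcatDataset) -> StateDecoding:
    """Viterbi path and posteriors for every segment of the dataset."""
    paths, posts = [], []
    for seg in data.segments:
        X = data.segment_values(seg)
        gamma, _ = forward_backward(params, X)
        paths.append(viterbi(params, X))
        posts.append(gamma)
    return StateDecoding(segments=list(data.segments), paths=paths,
                         posteriors=posts)


@dataclass
class SelectionRow:
    K: int
    aic: float
    loglik: float
    min_fo: float
    occupied: bool


@dataclass
class SelectionResult:
    rows: list[SelectionRow]
    recommended_K: int
    fits: dict[int, FitResult] = field(default_factory=dict)


def select_states(
    data: ConcatDataset | np.ndarray,
    K_list: Sequence[int],
    restarts: int = 5,
    max_iter: int = 200,
    seed: int = 0,
    occupancy_floor: float = 0.005,
) -> SelectionResult:
    """Fit each candidate K; recommend the AIC-minimal fully occupied model.

    A model is "fully occupied" when every state's fractional occupancy over
    the concatenated Viterbi decoding exceeds ``occupancy_floor``.  If no
    candidate qualifies, the AIC minimum over all candidates is returned.
    """
    if not K_list:
        raise ValueError("K_list must be non-empty")
    segs, segments = _as_segment_arrays(data)
    rows: list[SelectionRow] = []
    fits: dict[int, FitResult] = {}
    for i, K in enumerate(sorted(K_list)):
        fit = fit_hmm(data, K, restarts=restarts, max_iter=max_iter,
                      seed=seed + 1000 * i)
        all_states = np.concatenate([viterbi(fit.params, s) for s in segs])
        counts = np.bincount(all_states - 1, minlength=K)
        min_fo = float(counts.min() / counts.sum())
        rows.append(SelectionRow(K=K, aic=fit.aic, loglik=fit.loglik,
                                 min_fo=min_fo,
                                 occupied=min_fo > occupancy_floor))
        fits[K] = fit
    eligible = [r for r in rows if r.occupied] or rows
    recommended = min(eligible, key=lambda r: r.aic).K
    return SelectionResult(rows=rows, recommended_K=recommended, fits=fits)


def align_states(reference: HMMParams, other: HMMParams) -> np.ndarray:
    """Permutation matching other's states to the reference by mean similarity.

    Returns ``perm`` with ``perm[i]`` = index (0-based) of the state of
    ``other`` assigned to reference state ``i``, chosen to maximize the total
    Pearson correlation between matched state-mean vectors.
    """
    if reference.K != other.K:
        raise ValueError("state counts differ")
    ref = reference.state_means
    oth = other.state_means
    rz = (ref - ref.mean(axis=1, keepdims=True))
    oz = (oth - oth.mean(axis=1, keepdims=True))
    rn = np.linalg.norm(rz, axis=1, keepdims=True)
    on = np.linalg.norm(oz, axis=1, keepdims=True)
    rn[rn == 0] = 1.0
    on[on == 0] = 1.0
    C = (rz / rn) @ (oz / on).T
    _, cols = linear_sum_assignment(-C)
    return cols


def permute_params(params: HMMParams, perm: np.ndarray) -> HMMParams:
    """Relabel states so that new state i is old state perm[i]."""
    perm = np.asarray(perm)
    return HMMParams(
        initial_probs=params.initial_probs[perm],
        transition_matrix=params.transition_matrix[np.ix_(perm, perm)],
        state_means=params.state_means[perm],
        state_covariances=params.state_covariances[perm],
    )


def relabel_path(path: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply an alignment permutation to a 1-based state path.

    ``perm`` follows the :func:`align_states` convention, so old label
    ``perm[i]+1`` becomes new label ``i+1``.
    """
    inverse = np.empty_like(np.asarray(perm))
    inverse[np.asarray(perm)] = np.arange(len(perm))
    return inverse[np.asarray(path) - 1] + 1
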