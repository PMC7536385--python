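"""Coupling of decoded states to stimulus annotations and physiology.

Annotation intervals are binarized onto the TR grid and compared to each
state's expression vector with the Szymkiewicz-Simpson overlap,
|a & b| / min(|a|, |b|).  Significance comes from a permutation null that
shuffles the annotation vector (one shared shuffle per iteration across
subjects) and recomputes the subject-mean overlap.  Physiological traces
are segmented by the state path to give per-state deviations from the
run-mean baseline, tested against zero across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import expression_vectors


def binarize_annotations(
    intervals: np.ndarray | list[tuple[float, float]],
    tr_seconds: float,
    T: int,
) -> np.ndarray:
    """Binary TR track: TR t is set iff [t*TR, (t+1)*TR) meets any interval.

    Intervals are half-open (onset_s, offset_s) pairs in seconds.
    """
    track = np.zeros(T, dtype=bool)
    for onset, offset in np.atleast_2d(np.asarray(intervals, dtype=float)) \
            if len(intervals) else []:
        if offset <= onset:
            raise ValueError(f"interval offset {offset} <= onset {onset}")
        first = max(0, int(np.floor(onset / tr_seconds)))
        last = int(np.ceil(offset / tr_seconds))
        for t in range(first, min(last, T)):
            if onset < (t + 1) * tr_seconds and offset > t * tr_seconds:
                track[t] = True
    return track


def szymkiewicz_simpson(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap coefficient |a & b| / min(|a|, |b|); NaN if either is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return np.nan
    return float(np.sum(a & b) / min(na, nb))


@dataclass
class OverlapTestResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int


def overlap_permutation_test(
    state_vectors: np.ndarray,
    track: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    mode: str = "shuffle",
) -> OverlapTestResult:
    """Subject-mean Szymkiewicz-Simpson overlap against a permutation null.

    ``state_vectors`` is (n_subjects, T) binary.  Each permutation draws one
    random rearrangement of the annotation vector, shared across subjects,
    and recomputes the subject-mean overlap.  ``mode='shuffle'`` permutes
    the track uniformly at random; ``mode='circular'`` applies a random
    circular shift (autocorrelation-preserving alternative).  One-sided
    p = (1 + #{null >= observed}) / (n_perm + 1); z uses the null moments.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    V = np.asarray(state_vectors, dtype=bool)
    b = np.asarray(track, dtype=bool)
    T = b.size
    if V.shape[1] != T:
        raise ValueError("track length does not match state vectors")
    nb = int(b.sum())
    na = V.sum(axis=1)
    keep = na > 0
    if nb == 0 or keep.sum() < 2:
        raise ValueError("need a non-empty track and >= 2 non-empty subjects")
    V = V[keep]
    na = na[keep]
    denom = np.minimum(na, nb).astype(float)

    observed = float(np.mean((V & b).sum(axis=1) / denom))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if mode == "shuffle":
        perm_tracks = np.empty((n_perm, T), dtype=bool)
        for i in range(n_perm):
            perm_tracks[i] = b[rng.permutation(T)]
    elif mode == "circular":
        shifts = rng.integers(0, T, size=n_perm)
        idx = (np.arange(T)[None, :] - shifts[:, None]) % T
        perm_tracks = b[idx]
    else:
        raise ValueError("mode must be 'shuffle' or 'circular'")
    inter = V.astype(np.float64) @ perm_tracks.T.astype(np.float64)  # (n, P)
    null = (inter / denom[:, None]).mean(axis=0)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else np.inf
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return OverlapTestResult(observed, null_mean, null_sd, float(z), p,
                             n_perm, seed)


def fwe_threshold(alpha: float, K: int, n_categories: int) -> float:
    """Bonferroni per-test threshold over the states x categories family."""
    return alpha / (K * n_categories)


def overlap_family_test(
    paths: dict,
    tracks: dict,
    K: int,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overlap permutation test for every state x annotation category.

    ``paths`` maps subject -> 1-based movie path (equal lengths); ``tracks``
    maps category -> binary TR track.  Family-wise control is Bonferroni
    over the K * len(tracks) tests.
    """
    subjects = sorted(paths)
    expr = {s: expression_vectors(paths[s], K) for s in subjects}
    thr = fwe_threshold(alpha, K, len(tracks))
    rows = []
    for ci, (category, track) in enumerate(sorted(tracks.items())):
        for k in range(K):
            V = np.array([expr[s][k] for s in subjects])
            try:
                res = overlap_permutation_test(
                    V, track, n_perm=n_perm, seed=seed + 97 * (ci * K + k)
                )
            except ValueError:
                rows.append(dict(state=k + 1, category=category,
                                 overlap=np.nan, z=np.nan, p=np.nan,
                                 significant_fwe=False))
                continue
            rows.append(dict(state=k + 1, category=category,
                             overlap=res.observed, z=res.z, p=res.p,
                             significant_fwe=bool(res.p < thr)))
    return pd.DataFrame(rows)


def physio_state_deviation(
    trace: np.ndarray, path: np.ndarray, K: int
) -> np.ndarray:
    """Per-state deviation of a physiological trace from its run mean.

    delta_k = mean(trace | state k) - mean(trace); NaN for unvisited states.
    By construction sum_k FO_k * delta_k = 0.
    """
    trace = np.asarray(trace, dtype=float)
    path = np.asarray(path, dtype=int)
    if trace.size != path.size:
        raise ValueError("trace and path must be aligned")
    baseline = trace.mean()
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        sel = path == k
        if sel.any():
            out[k - 1] = trace[sel].mean() - baseline
    return out


def group_physio_test(
    deltas: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sample two-sided t-test of per-subject deviations against zero.

    ``deltas`` is (n_subjects, K); subjects missing a state are dropped for
    that state.  Bonferroni correction over the K states.
    """
    deltas = np.asarray(deltas, dtype=float)
    n, K = deltas.shape
    rows = []
    for k in range(K):
        col = deltas[:, k]
        col = col[np.isfinite(col)]
        if col.size < 3:
            rows.append(dict(state=k + 1, mean_delta=np.nan, t=np.nan,
                             p=np.nan, n=col.size, significant_fwe=False))
            continue
        t, p = stats.ttest_1samp(col, 0.0)
        rows.append(dict(state=k + 1, mean_delta=float(col.mean()),
                         t=float(t), p=float(p), n=col.size,
                         significant_fwe=bool(p < alpha / K)))
    return pd.DataFrame(rows)


def correlate_traces(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two TR-aligned traces, with exact p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("traces must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance trace")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
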