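"""Per-run dynamics metrics and rest-vs-movie contrasts.

Fractional occupancy, dwell times and empirical transition matrices are
computed from 1-based Viterbi state paths, one run at a time (transitions
never cross run boundaries).  Group contrasts use paired t-tests with
Bonferroni correction over states, and a network-based permutation statistic
on the transition graph (threshold edge t-values, measure weakly connected
component sizes, compare against a sign-flip null of maximum component
sizes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def _check_path(path: np.ndarray, K: int) -> np.ndarray:
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("empty state path")
    if path.min() < 1 or path.max() > K:
        raise ValueError(f"state labels must lie in 1..{K}")
    return path


def fractional_occupancy(path: np.ndarray, K: int) -> np.ndarray:
    """Fraction of timepoints spent in each state; sums to 1."""
    path = _check_path(path, K)
    return np.bincount(path - 1, minlength=K) / path.size


def visit_lengths(path: np.ndarray, K: int) -> list[list[int]]:
    """Maximal-run lengths (in TRs) per state, in order of occurrence."""
    path = _check_path(path, K)
    visits: list[list[int]] = [[] for _ in range(K)]
    edges = np.flatnonzero(np.diff(path)) + 1
    starts = np.r_[0, edges]
    stops = np.r_[edges, path.size]
    for a, b in zip(starts, stops):
        visits[path[a] - 1].append(int(b - a))
    return visits


def dwell_times(
    path: np.ndarray, tr_seconds: float, K: int
) -> tuple[list[list[int]], np.ndarray]:
    """Per-state visit lengths and mean visit duration in seconds.

    Unvisited states have NaN mean dwell.
    """
    visits = visit_lengths(path, K)
    mean_s = np.array(
        [tr_seconds * np.mean(v) if v else np.nan for v in visits]
    )
    return visits, mean_s


def empirical_transitions(path: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized transition counts; rows with no outgoing pairs are NaN."""
    path = _check_path(path, K)
    counts = np.zeros((K, K))
    np.add.at(counts, (path[:-1] - 1, path[1:] - 1), 1.0)
    rows = counts.sum(axis=1)
    out = np.full((K, K), np.nan)
    ok = rows > 0
    out[ok] = counts[ok] / rows[ok, None]
    return out


def summarize_dynamics(
    paths: dict, tr_seconds: float, K: int
) -> pd.DataFrame:
    """Tidy per subject/session/condition/state summary table.

    ``paths`` maps (subject, session, condition) -> 1-based path.
    """
    rows = []
    for (sub, ses, cond), path in sorted(paths.items()):
        fo = fractional_occupancy(path, K)
        visits, mean_s = dwell_times(path, tr_seconds, K)
        for k in range(K):
            rows.append(
                dict(subject=sub, session=ses, condition=cond, state=k + 1,
                     fo=fo[k], mean_dwell_s=mean_s[k],
                     visit_count=len(visits[k]))
            )
    return pd.DataFrame(rows)


def threshold_transitions(
    mean_matrix: np.ndarray, top_frac: float = 0.2
) -> list[tuple[int, int]]:
    """Most frequent off-diagonal transitions (top ``top_frac`` by weight).

    Keeps the ceil(top_frac * m) heaviest of the m off-diagonal edges; ties
    with the cut-off weight are all retained.  Edges are returned as 1-based
    (from, to) pairs.
    """
    M = np.asarray(mean_matrix, dtype=float)
    K = M.shape[0]
    off = [(i, j) for i in range(K) for j in range(K) if i != j]
    weights = np.array([M[i, j] for i, j in off])
    weights = np.where(np.isnan(weights), -np.inf, weights)
    n_keep = int(np.ceil(top_frac * len(off)))
    cut = np.sort(weights)[::-1][n_keep - 1]
    return [(i + 1, j + 1) for (i, j), w in zip(off, weights) if w >= cut]


def paired_state_contrast(
    table: pd.DataFrame,
    value: str = "fo",
    condition_a: str = "movie",
    condition_b: str = "rest",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-state paired two-sided t-test between conditions.

    Sessions are averaged within subject first.  Significance uses the
    Bonferroni-corrected threshold alpha / K.  Subjects missing either
    condition are dropped with a warning.
    """
    K = int(table["state"].max())
    for cond in (condition_a, condition_b):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} absent from table")
    wide = (
        table.groupby(["subject", "condition", "state"])[value]
        .mean()
        .unstack("condition")
    )
    per_subject = wide.groupby(level="subject").count()
    incomplete = per_subject[
        (per_subject[[condition_a, condition_b]] == 0).any(axis=1)
    ].index
    if len(incomplete):
        warnings.warn(
            f"dropping subjects without both conditions: {sorted(incomplete)}"
        )
        wide = wide.drop(index=incomplete, level="subject")
    rows = []
    for k in range(1, K + 1):
        sub = wide.xs(k, level="state")[[condition_a, condition_b]].dropna()
        a, b = sub[condition_a].values, sub[condition_b].values
        if len(a) < 3:
            # metric undefined for enough subjects (e.g. dwell time of a
            # state they never visit): no test for this state
            rows.append(dict(state=k, t=np.nan, p=np.nan, significant=False,
                             mean_a=np.nan, mean_b=np.nan, n_pairs=len(a)))
            continue
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append(dict(state=k, t=float(t), p=float(p),
                         significant=bool(p < alpha / K),
                         mean_a=float(a.mean()), mean_b=float(b.mean()),
                         n_pairs=len(a)))
    return pd.DataFrame(rows)


@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]    # 1-based directed edges
    size: int                       # edge count
    p_fwe: float


@dataclass
class TransitionContrastResult:
    """Network-based statistic on the rest/movie transition-graph contrast."""

    t_stats: np.ndarray                       # K x K, NaN on diagonal
    components_a_gt_b: list[NbsComponent]
    components_b_gt_a: list[NbsComponent]
    primary_t: float
    n_perm: int
    exhaustive: bool
    seed: int


def _edge_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t over subjects for each edge column; NaN-safe."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _components(mask_flat: np.ndarray, off_idx: np.ndarray, K: int
                ) -> list[list[tuple[int, int]]]:
    """Weakly connected components (edge lists) of a thresholded edge mask."""
    sel = np.flatnonzero(mask_flat)
    if sel.size == 0:
        return []
    ii, jj = off_idx[0][sel], off_idx[1][sel]
    sym = csr_matrix(
        (np.ones(2 * sel.size), (np.r_[ii, jj], np.r_[jj, ii])), shape=(K, K)
    )
    n_comp, labels = connected_components(sym, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(ii, jj):
        comps.setdefault(labels[a], []).append((int(a) + 1, int(b) + 1))
    return list(comps.values())


def _max_component_size(mask_flat: np.ndarray, off_idx: np.ndarray, K: int
                        ) -> int:
    comps = _components(mask_flat, off_idx, K)
    return max((len(c) for c in comps), default=0)


def nbs_transition_contrast(
    mats_a: np.ndarray,
    mats_b: np.ndarray,
    primary_t: float,
    n_perm: int = 5000,
    seed: int = 0,
) -> TransitionContrastResult:
    """Network-based statistic on paired per-subject transition matrices.

    ``mats_a``/``mats_b`` are (n, K, K) per-subject matrices for the two
    conditions (diagonal excluded).  Per directed edge a paired t statistic
    is computed; edges exceeding ``primary_t`` form a graph whose weakly
    connected components are scored by edge count.  The null distribution of
    the maximum component size comes from within-subject condition-label
    sign flips; when 2^n <= n_perm all flips are enumerated, otherwise
    ``n_perm`` random flips are sampled.  Both contrast directions share the
    (symmetric) null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    A = np.asarray(mats_a, dtype=float)
    B = np.asarray(mats_b, dtype=float)
    if A.shape != B.shape or A.ndim != 3:
        raise ValueError("need matched (n, K, K) matrix stacks")
    n, K, _ = A.shape
    off_idx = np.where(~np.eye(K, dtype=bool))
    dA = A[:, off_idx[0], off_idx[1]]
    dB = B[:, off_idx[0], off_idx[1]]
    diffs = dA - dB                       # (n, E)
    valid = np.isfinite(diffs).all(axis=0)

    def thresholded(d: np.ndarray, sign: float) -> np.ndarray:
        t = _edge_t(sign * d)
        t = np.where(valid, t, -np.inf)
        return t > primary_t

    t_obs = _edge_t(diffs)
    t_mat = np.full((K, K), np.nan)
    t_mat[off_idx] = np.where(valid, t_obs, np.nan)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    null_max = np.empty(len(signs), dtype=int)
    for s_i, s in enumerate(signs):
        flipped = diffs * s[:, None]
        null_max[s_i] = _max_component_size(
            thresholded(flipped, 1.0), off_idx, K
        )

    def score(sign: float) -> list[NbsComponent]:
        comps = _components(thresholded(diffs, sign), off_idx, K)
        out = []
        for edges in comps:
            size = len(edges)
            if exhaustive:
                p = float(np.mean(null_max >= size))
            else:
                p = float((1 + np.sum(null_max >= size)) / (len(signs) + 1))
            out.append(NbsComponent(edges=edges, size=size, p_fwe=p))
        out.sort(key=lambda c: -c.size)
        return out

    return TransitionContrastResult(
        t_stats=t_mat,
        components_a_gt_b=score(1.0),
        components_b_gt_a=score(-1.0),
        primary_t=primary_t,
        n_perm=len(signs),
        exhaustive=exhaustive,
        seed=seed,
    )
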