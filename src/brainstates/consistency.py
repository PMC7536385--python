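"""Agreement of state paths across participants and sessions.

A state path is re-expressed as K binary expression vectors (state present
at that TR or not).  Inter-subject agreement uses a centred sliding window:
within the window each state counts the participants expressing it at least
once, and the consistency at that TR is the maximal count as a percentage.
Cross-session and cross-subject agreement use per-state Jaccard overlap of
the expression vectors, averaged over the states present.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.ndimage import maximum_filter1d


def expression_vectors(path: np.ndarray, K: int) -> np.ndarray:
    """Binary (K, T) matrix; row k is 1 where state k+1 is expressed."""
    path = np.asarray(path, dtype=int)
    if path.min() < 1 or path.max() > K:
        raise ValueError(f"state labels must lie in 1..{K}")
    out = np.zeros((K, path.size), dtype=bool)
    out[path - 1, np.arange(path.size)] = True
    return out


def sliding_consistency(
    paths: np.ndarray, K: int, window_volumes: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Per-TR inter-subject consistency (percent) and modal state.

    ``paths`` is (n_subjects, T).  The window is centred and truncated at
    the run edges.  For each state the number of subjects expressing it at
    least once in the window is counted; consistency is 100 * max count / n
    and the modal state is the lowest-index state attaining it.
    """
    paths = np.asarray(paths, dtype=int)
    n, T = paths.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if window_volumes > T:
        raise ValueError("window longer than the run")
    counts = np.zeros((K, T))
    for i in range(n):
        expr = expression_vectors(paths[i], K)
        # max filter with zero padding == "expressed at least once" in the
        # centred, edge-truncated window
        win = maximum_filter1d(
            expr.astype(np.uint8), size=window_volumes, axis=1,
            mode="constant", cval=0,
        )
        counts += win
    modal = counts.argmax(axis=0)          # lowest index wins ties
    percent = 100.0 * counts[modal, np.arange(T)] / n
    return percent, modal + 1


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a & b| / |a | b| of two binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.sum(a | b)
    if union == 0:
        return np.nan
    return float(np.sum(a & b) / union)


def cross_session_jaccard(
    path_a: np.ndarray, path_b: np.ndarray, K: int
) -> tuple[np.ndarray, float]:
    """Per-state Jaccard between two sessions' paths, and their mean.

    States absent from both sessions are excluded from the mean (NaN in the
    per-state vector).
    """
    pa = np.asarray(path_a)
    pb = np.asarray(path_b)
    if pa.size != pb.size:
        raise ValueError("session paths must have equal length")
    ea = expression_vectors(pa, K)
    eb = expression_vectors(pb, K)
    per_state = np.array([jaccard(ea[k], eb[k]) for k in range(K)])
    return per_state, float(np.nanmean(per_state))


def consistency_contrast(
    jaccard_movie: np.ndarray, jaccard_rest: np.ndarray
) -> tuple[float, float, int]:
    """Paired two-sided t-test of per-subject mean Jaccard, movie vs rest.

    Returns (t, p, degrees of freedom).
    """
    a = np.asarray(jaccard_movie, dtype=float)
    b = np.asarray(jaccard_rest, dtype=float)
    if a.size != b.size:
        raise ValueError("per-subject vectors must be paired")
    if a.size < 2:
        raise ValueError("need at least 2 subjects for a paired test")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), a.size - 1


def path_dissimilarity(
    path_i: np.ndarray, path_j: np.ndarray, K: int
) -> float:
    """1 - mean per-state Jaccard between two subjects' paths, in [0, 1].

    The mean runs over states expressed by at least one of the two subjects.
    """
    pi = np.asarray(path_i)
    pj = np.asarray(path_j)
    if pi.size != pj.size:
        raise ValueError("paths must have equal length")
    ei = expression_vectors(pi, K)
    ej = expression_vectors(pj, K)
    js = [jaccard(ei[k], ej[k]) for k in range(K)
          if ei[k].any() or ej[k].any()]
    return float(1.0 - np.mean(js))
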