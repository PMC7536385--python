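"""Inter-subject representational similarity of brain dynamics and ratings.

Subject-pairwise distance matrices summarize individual differences:
Euclidean distance on questionnaire ratings, correlation distance (1 - r)
on fractional-occupancy and transition-matrix features, and Jaccard path
dissimilarity on Viterbi paths.  Correspondence between two representations
is the Pearson correlation of their strictly-lower triangles, with a
Mantel-style permutation test (joint row/column relabelling of one matrix).
Questionnaires are embedded in 2D by classical (Torgerson) MDS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .consistency import path_dissimilarity


def _check_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return D


def questionnaire_distance(ratings: np.ndarray) -> np.ndarray:
    """Euclidean distance between subjects' questionnaire rating vectors."""
    R = np.asarray(ratings, dtype=float)
    return squareform(pdist(R, metric="euclidean"))


def _correlation_distance(features: np.ndarray) -> np.ndarray:
    F = np.asarray(features, dtype=float)
    sd = F.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"zero-variance feature vector for subject {bad}")
    C = np.corrcoef(F)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return D


def fo_distance(fo: np.ndarray) -> np.ndarray:
    """Correlation distance (1 - Pearson r) between subjects' FO profiles."""
    return _correlation_distance(fo)


def transition_distance(matrices: np.ndarray) -> np.ndarray:
    """Correlation distance between flattened off-diagonal transition rows.

    ``matrices`` is (n, K, K); each subject contributes the K*(K-1)
    off-diagonal entries as a feature vector.
    """
    M = np.asarray(matrices, dtype=float)
    n, K, _ = M.shape
    off = ~np.eye(K, dtype=bool)
    feats = M[:, off]
    feats = np.nan_to_num(feats, nan=0.0)   # unvisited-state rows count as 0
    return _correlation_distance(feats)


def path_distance_matrix(paths: np.ndarray, K: int) -> np.ndarray:
    """Pairwise Jaccard path dissimilarity between subjects."""
    P = np.asarray(paths, dtype=int)
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = path_dissimilarity(P[i], P[j], K)
    return D


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray   # (n, dims)
    eigenvalues: np.ndarray   # all n eigenvalues, descending


def classical_mds(D: np.ndarray, dims: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres the squared distances, eigendecomposes the Gram matrix
    and keeps the top ``dims`` non-negative eigenpairs.  Sign convention:
    on each axis the coordinate of largest magnitude is positive.
    """
    D = _check_square(D)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for an embedding")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    for a in range(dims):
        lam = max(vals[a], 0.0)
        axis = vecs[:, a] * math.sqrt(lam)
        top = np.argmax(np.abs(axis))
        if axis[top] < 0:
            axis = -axis
        coords[:, a] = axis
    return MdsEmbedding(coordinates=coords, eigenvalues=vals)


@dataclass
class MantelResult:
    r: float
    z: float
    p: float
    n_perm: int
    exhaustive: bool
    seed: int


def _lower(D: np.ndarray) -> np.ndarray:
    return D[np.tril_indices(D.shape[0], k=-1)]


def mantel_correlation(
    D1: np.ndarray, D2: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> MantelResult:
    """Pearson r between lower triangles with a subject-relabelling null.

    Each permutation applies one random relabelling jointly to the rows and
    columns of ``D2``.  When n! <= n_perm all relabellings are enumerated
    (p = fraction of the full null, identity included, with r at least the
    observed); otherwise p = (1 + #{null >= r}) / (n_perm + 1).
    """
    D1 = _check_square(D1)
    D2 = _check_square(D2)
    n = D1.shape[0]
    if D2.shape[0] != n:
        raise ValueError("matrices must share subject ordering")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    x = _lower(D1)
    if x.std() == 0:
        raise ValueError("degenerate distance matrix (constant)")

    def corr_with(perm: np.ndarray) -> float:
        y = _lower(D2[np.ix_(perm, perm)])
        if y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr_with(np.arange(n))
    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        null = np.array(
            [corr_with(np.array(p))
             for p in itertools.permutations(range(n))]
        )
        p = float(np.mean(null >= r_obs))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        null = np.array(
            [corr_with(rng.permutation(n)) for _ in range(n_perm)]
        )
        p = float((1 + np.sum(null >= r_obs)) / (n_perm + 1))
    sd = null.std(ddof=1)
    z = (r_obs - null.mean()) / sd if sd > 0 else np.inf
    return MantelResult(r=r_obs, z=float(z), p=p, n_perm=len(null),
                        exhaustive=exhaustive, seed=seed)
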