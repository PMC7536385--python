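"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a multi-session naturalistic-viewing study design:
each subject contributes a resting-state run and a movie run per session.
Rest runs are subject-idiosyncratic Markov chains concentrated on a small
set of dominant states (bistable by default); movie runs copy a single
stimulus-locked master state sequence, degraded per subject by a circular
temporal jitter and per-TR flips.  Emissions are state-specific Gaussians.
Heart-rate and pupil traces carry state-conditioned offsets, pupil diameter
couples negatively to a scene-luminance track, and post-movie questionnaire
ratings are monotone in a latent per-subject engagement score.

Engagement also degrades stimulus locking: less engaged subjects flip away
from the master path more often, so their occupancy profiles drift, which
is what couples brain dynamics to ratings for the inter-subject analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import hadamard

from .dataio import RunTimeSeries, write_run
from .hmm import HMMParams

# Multiplier converting (1 - engagement) into extra flip mass, relative to
# the baseline flip probability.
_ENGAGEMENT_FLIP_GAIN = 6.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults mirror a 14-subject, two-session design with an 8-min rest run
    (220 volumes) and a 20-min movie run (535 volumes) at TR 2.2 s, reduced
    to D=14 network channels, with ten generating states of which two
    dominate rest.
    """

    n_subjects: int = 14
    n_sessions: int = 2
    K_true: int = 10
    D: int = 14
    T_rest: int = 220
    T_movie: int = 535
    tr_seconds: float = 2.2
    rest_self_prob: float = 0.9
    # 1-based labels; None picks states (5, 9) when K_true allows, else (1, 2)
    rest_dominant_states: tuple[int, ...] | None = None
    movie_self_prob: float = 0.75
    jitter_tr: int = 2
    flip_prob: float = 0.05
    mean_separation: float = 2.0
    cov_scale: float = 1.0
    physio_offsets: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    engagement_coupling: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if self.T_rest < 20 or self.T_movie < 20:
            raise ValueError("runs must have at least 20 timepoints")
        for p in (self.rest_self_prob, self.movie_self_prob, self.flip_prob,
                  self.engagement_coupling):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rest_dominant_states is None:
            default_dom = (5, 9) if self.K_true >= 9 else (1, 2)
            object.__setattr__(self, "rest_dominant_states", default_dom)
        dom = set(self.rest_dominant_states)
        if not dom or not dom <= set(range(1, self.K_true + 1)):
            raise ValueError(
                "rest_dominant_states must be a nonempty subset of 1..K_true"
            )
        if self.cov_scale <= 0:
            raise ValueError("cov_scale must be positive")
        if self.jitter_tr < 0:
            raise ValueError("jitter_tr must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows, kept for recovery tests."""

    config: SimConfig
    true_params: HMMParams          # emission model + rest-chain transitions
    movie_transition_matrix: np.ndarray
    master_movie_path: np.ndarray   # (T_movie,), 1-based, shared pre-jitter
    paths: dict                     # (subject, session, condition) -> path
    engagement: np.ndarray          # (n_subjects,), in [0, 1]
    hr_offsets: np.ndarray          # (K,), bpm
    pd_offsets: np.ndarray          # (K,), a.u.
    hr_baseline: float = 70.0
    pd_baseline: float = 3.0

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.paths})


def default_physio_offsets(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-state (dHR bpm, dPD a.u.) offsets.

    One clear bradycardic and one tachycardic state plus two pupil-coupled
    states; the remaining states sit at baseline.
    """
    hr = np.zeros(K)
    pd_ = np.zeros(K)
    hr[1 % K] = 5.0      # state 2: raised heart rate
    hr[2 % K] = -3.0     # state 3: lowered heart rate
    pd_[0] = 0.3         # state 1: dilated pupil
    pd_[3 % K] = -0.4    # state 4: constricted pupil
    return hr, pd_


def state_mean_patterns(K: int, D: int, separation: float) -> np.ndarray:
    """Near-orthogonal +/- pattern vectors with pairwise distance ~separation.

    Rows of a Hadamard matrix (the all-ones row excluded) are truncated to D
    channels, orthonormalised when K <= D (kept as normalised +/- patterns
    otherwise), and scaled by ``separation``: each state mean has norm
    ``separation`` in units of the unit emission SD, so orthogonal pairs sit
    sqrt(2)*separation apart.
    """
    P = 1
    while P < max(K + 1, D):
        P *= 2
    H = hadamard(P).astype(float)
    M = H[1:K + 1, :D]
    if K <= D:
        Q, R = np.linalg.qr(M.T)           # columns of Q span the patterns
        Q = Q * np.sign(np.diag(R))        # deterministic sign convention
        M = Q.T
    else:
        M /= np.linalg.norm(M, axis=1, keepdims=True)
    return separation * M


def rest_transition_matrix(
    K: int, dominant: Sequence[int], self_prob: float
) -> np.ndarray:
    """Row-stochastic rest chain concentrated on the dominant states.

    Dominant states keep ``self_prob`` on the diagonal and send 90% of the
    remaining mass to the other dominant states (all of it if there are
    none others); non-dominant states are transient and fall back to the
    dominant set quickly.
    """
    dom = sorted(d - 1 for d in dominant)
    non = [k for k in range(K) if k not in dom]
    A = np.zeros((K, K))
    for i in dom:
        others = [j for j in dom if j != i]
        A[i, i] = self_prob
        rem = 1.0 - self_prob
        if others and non:
            for j in others:
                A[i, j] = 0.9 * rem / len(others)
            for j in non:
                A[i, j] = 0.1 * rem / len(non)
        elif others:
            for j in others:
                A[i, j] = rem / len(others)
        else:
            for j in non:
                A[i, j] = rem / len(non)
    for i in non:
        A[i, i] = 0.2
        for j in dom:
            A[i, j] = 0.8 / len(dom)
    return A / A.sum(axis=1, keepdims=True)


def movie_transition_matrix(K: int, self_prob: float) -> np.ndarray:
    """Uniform sticky chain generating the master movie state sequence."""
    A = np.full((K, K), (1.0 - self_prob) / (K - 1))
    np.fill_diagonal(A, self_prob)
    return A


def _simulate_chain(
    A: np.ndarray, pi: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a 1-based Markov path of length T."""
    K = A.shape[0]
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(K, p=pi)
    for t in range(1, T):
        path[t] = rng.choice(K, p=A[path[t - 1]])
    return path + 1


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def _network_labels(D: int) -> list[str]:
    return [f"BN{i + 1:02d}" for i in range(D)]


def generate_cohort(
    config: SimConfig,
) -> tuple[list[RunTimeSeries], GroundTruth]:
    """Simulate all runs of a cohort plus the generating ground truth.

    Identical config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    K, D = config.K_true, config.D
    means = state_mean_patterns(K, D, config.mean_separation)
    covs = np.repeat((config.cov_scale * np.eye(D))[None], K, axis=0)
    A_rest = rest_transition_matrix(
        K, config.rest_dominant_states, config.rest_self_prob
    )
    A_movie = movie_transition_matrix(K, config.movie_self_prob)
    dom0 = [d - 1 for d in config.rest_dominant_states]
    pi_rest = np.zeros(K)
    pi_rest[dom0] = 1.0 / len(dom0)
    true_params = HMMParams(pi_rest, A_rest, means, covs)

    master = _simulate_chain(A_movie, np.full(K, 1.0 / K), config.T_movie, rng)
    engagement = rng.uniform(0.0, 1.0, size=config.n_subjects)

    if config.physio_offsets is None:
        hr_off, pd_off = default_physio_offsets(K)
    else:
        hr_off = np.asarray(config.physio_offsets[0], dtype=float)
        pd_off = np.asarray(config.physio_offsets[1], dtype=float)
        if hr_off.shape != (K,) or pd_off.shape != (K,):
            raise ValueError("physio_offsets must provide one value per state")

    labels = _network_labels(D)
    subjects = _subject_ids(config.n_subjects)
    sessions = ["A", "B"][: config.n_sessions] or ["A"]
    if config.n_sessions > 2:
        sessions = [chr(ord("A") + i) for i in range(config.n_sessions)]

    runs: list[RunTimeSeries] = []
    paths: dict = {}
    noise_scale = np.sqrt(config.cov_scale)
    for si, sub in enumerate(subjects):
        eng = engagement[si]
        eff_flip = min(
            0.9,
            config.flip_prob
            * (1.0 + _ENGAGEMENT_FLIP_GAIN * config.engagement_coupling
               * (1.0 - eng)),
        )
        for ses in sessions:
            # rest: idiosyncratic bistable chain
            rest_path = _simulate_chain(A_rest, pi_rest, config.T_rest, rng)
            # movie: master path + circular jitter + flips
            shift = int(rng.integers(-config.jitter_tr, config.jitter_tr + 1))
            movie_path = np.roll(master, shift)
            flips = rng.random(config.T_movie) < eff_flip
            if flips.any():
                # a flip is a momentary lapse from the stimulus into the
                # subject's intrinsic rest dynamics: half the flips land on
                # a rest-dominant state, half deviate uniformly
                n_flip = int(flips.sum())
                to_rest = rng.random(n_flip) < 0.5
                targets = np.empty(n_flip, dtype=int)
                dom = np.asarray(config.rest_dominant_states)
                targets[to_rest] = dom[
                    rng.integers(0, len(dom), size=int(to_rest.sum()))
                ]
                offs = rng.integers(1, K, size=int((~to_rest).sum()))
                targets[~to_rest] = (
                    movie_path[flips][~to_rest] - 1 + offs
                ) % K + 1
                movie_path = movie_path.copy()
                movie_path[flips] = targets
            for cond, path, T in (
                ("rest", rest_path, config.T_rest),
                ("movie", movie_path, config.T_movie),
            ):
                values = means[path - 1] + noise_scale * rng.standard_normal(
                    (T, D)
                )
                runs.append(
                    RunTimeSeries(
                        subject_id=sub, session=ses, condition=cond,
                        tr_seconds=config.tr_seconds,
                        network_labels=list(labels), values=values,
                    )
                )
                paths[(sub, ses, cond)] = path

    truth = GroundTruth(
        config=config,
        true_params=true_params,
        movie_transition_matrix=A_movie,
        master_movie_path=master,
        paths=paths,
        engagement=engagement,
        hr_offsets=hr_off,
        pd_offsets=pd_off,
    )
    return runs, truth


def sample_hmm_dataset(
    params: HMMParams,
    n_segments: int,
    T: int,
    seed: int = 0,
    subject_prefix: str = "seg",
) -> tuple["object", list[np.ndarray]]:
    """Plain HMM sequences for recovery tests: Markov paths + Gaussian noise.

    Returns a :class:`~brainstates.dataio.ConcatDataset` of ``n_segments``
    independent segments of length ``T`` drawn from ``params``, together
    with the true 1-based paths.
    """
    from .dataio import ConcatDataset, Segment

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    K, D = params.K, params.D
    chols = np.linalg.cholesky(params.state_covariances)
    blocks, segments, paths = [], [], []
    pos = 0
    for s in range(n_segments):
        path = _simulate_chain(
            params.transition_matrix, params.initial_probs, T, rng
        )
        noise = rng.standard_normal((T, D))
        values = params.state_means[path - 1] + np.einsum(
            "tij,tj->ti", chols[path - 1], noise
        )
        blocks.append(values)
        segments.append(
            Segment(f"{subject_prefix}-{s + 1:02d}", "A", "sim", pos, T)
        )
        paths.append(path)
        pos += T
    data = ConcatDataset(
        values=np.vstack(blocks), segments=segments,
        network_labels=_network_labels(D),
    )
    return data, paths


def attach_annotations(
    truth: GroundTruth, category_map: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Annotation intervals covering the master-path epochs of each category.

    ``category_map`` assigns each category a set of 1-based states; the
    returned table has columns (category, onset_s, offset_s) with half-open
    intervals in seconds.  An empty state set yields an empty track.
    """
    K = truth.config.K_true
    tr = truth.config.tr_seconds
    master = truth.master_movie_path
    rows = []
    for category, states in category_map.items():
        sset = set(states)
        if not sset <= set(range(1, K + 1)):
            raise ValueError(f"category {category!r} references invalid states")
        member = np.isin(master, list(sset))
        if member.any():
            edges = np.flatnonzero(np.diff(member.astype(int)))
            starts = np.r_[0, edges + 1]
            stops = np.r_[edges + 1, len(master)]
            for a, b in zip(starts, stops):
                if member[a]:
                    rows.append((category, a * tr, b * tr))
    return pd.DataFrame(rows, columns=["category", "onset_s", "offset_s"])


def attach_physio(
    truth: GroundTruth,
    noise_sd: float = 0.5,
    ar_coeff: float = 0.3,
    lum_coupling: float = 0.5,
    seed: int | None = None,
) -> dict:
    """TR-resolution physiological traces for every movie run.

    Returns ``{(subject, session): {"hr": ..., "pd": ..., "luminance": ...}}``.
    Each trace is baseline + per-state offset + stationary AR(1) noise;
    pupil diameter additionally couples negatively to a shared luminance
    track (PD = a - b*luminance + noise with b = ``lum_coupling``).
    """
    if not (0.0 <= ar_coeff < 1.0):
        raise ValueError("ar_coeff must lie in [0, 1) for stationarity")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    cfg = truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed + 101 if seed is None else seed)
    )
    T = truth.master_movie_path.size

    def ar1(n: int, sd: float) -> np.ndarray:
        if sd == 0.0:
            return np.zeros(n)
        x = np.empty(n)
        innov = np.sqrt(1.0 - ar_coeff**2) * sd
        x[0] = sd * rng.standard_normal()
        for t in range(1, n):
            x[t] = ar_coeff * x[t - 1] + innov * rng.standard_normal()
        return x

    # shared scene-luminance track: slowly varying, positive
    lum = 1.0 + 0.5 * np.abs(ar1(T, 1.0)) if noise_sd > 0 else np.ones(T)
    lum_centred = lum - lum.mean()

    out: dict = {}
    for (sub, ses, cond), path in truth.paths.items():
        if cond != "movie":
            continue
        hr = truth.hr_baseline + truth.hr_offsets[path - 1] + ar1(T, noise_sd)
        pd_trace = (
            truth.pd_baseline
            + truth.pd_offsets[path - 1]
            - lum_coupling * lum_centred
            + ar1(T, noise_sd)
        )
        out[(sub, ses)] = {"hr": hr, "pd": pd_trace, "luminance": lum.copy()}
    return out


def attach_questionnaire(
    truth: GroundTruth, coupling: float | None = None
) -> pd.DataFrame:
    """Post-movie ratings (1..5) monotone in latent engagement.

    ``coupling`` in [0, 1] blends the engagement signal with independent
    uniform noise: 1 gives deterministic monotone ratings, 0 gives ratings
    independent of engagement.  Boredom decreases with engagement;
    enjoyment, emotion and audio quality increase.
    """
    cfg = truth.config
    if coupling is None:
        coupling = cfg.engagement_coupling
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 202))
    subjects = truth.subjects()
    eng = truth.engagement
    rows = []
    for i, sub in enumerate(subjects):
        u = rng.uniform(0.0, 1.0, size=4)
        latent = coupling * eng[i] + (1.0 - coupling) * u
        boredom = int(np.clip(round(1 + 4 * (1 - latent[0])), 1, 5))
        enjoyment = int(np.clip(round(1 + 4 * latent[1]), 1, 5))
        emotion = int(np.clip(round(1 + 4 * latent[2]), 1, 5))
        audio = int(np.clip(round(1 + 4 * latent[3]), 1, 5))
        rows.append((sub, boredom, enjoyment, emotion, audio))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "boredom", "enjoyment", "emotion",
                 "audio_quality"],
    )


DEFAULT_CATEGORY_MAP: dict[str, tuple[int, ...]] = {
    "faces_positive": (1,),
    "faces_negative": (6,),
    "scenes_positive": (1, 2),
    "scenes_negative": (8,),
    "language": (3,),
    "changepoint": (2, 7),
}


def write_cohort(
    out_dir: str | Path,
    runs: Sequence[RunTimeSeries],
    truth: GroundTruth,
    annotations: pd.DataFrame | None = None,
    physio: dict | None = None,
    questionnaire: pd.DataFrame | None = None,
) -> Path:
    """Serialize a cohort to one directory of plain-text artifacts."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    for run in runs:
        name = f"{run.subject_id}_ses-{run.session}_{run.condition}.tsv"
        write_run(run, out / "runs" / name)
    if annotations is not None:
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    if physio is not None:
        pdir = out / "physio"
        pdir.mkdir(exist_ok=True)
        for (sub, ses), traces in physio.items():
            for kind, values in traces.items():
                df = pd.DataFrame(
                    {"time_index": np.arange(len(values)), "value": values}
                )
                df.to_csv(
                    pdir / f"{sub}_ses-{ses}_{kind}.tsv", sep="\t", index=False
                )
    if questionnaire is not None:
        questionnaire.to_csv(out / "questionnaire.csv", index=False)
    gt = {
        "master_movie_path": truth.master_movie_path.tolist(),
        "engagement": truth.engagement.tolist(),
        "hr_offsets": truth.hr_offsets.tolist(),
        "pd_offsets": truth.pd_offsets.tolist(),
        "hr_baseline": truth.hr_baseline,
        "pd_baseline": truth.pd_baseline,
        "movie_transition_matrix": truth.movie_transition_matrix.tolist(),
        "true_params": truth.true_params.to_dict(),
        "paths": {
            "|".join(k): v.tolist() for k, v in truth.paths.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    cfg = asdict(truth.config)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out
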