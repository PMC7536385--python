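"""End-to-end orchestration: simulate -> preprocess -> fit -> statistics.

Every stage reads its inputs from, and writes its outputs to, one artifact
directory, so the pipeline is re-entrant: a stage can be re-run from the
serialized artifacts of the previous one.  All randomness flows through
named seeds recorded in the echoed config, and outputs are stamped with a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency as cons
from . import coupling as coup
from . import dynamics as dyn
from . import isrsa
from .dataio import PreparedRun, concatenate, prepare_run, read_run, write_run
from .hmm import HMMParams, decode, fit_hmm, relabel_path, align_states
from .simulate import (
    DEFAULT_CATEGORY_MAP,
    SimConfig,
    attach_annotations,
    attach_physio,
    attach_questionnaire,
    generate_cohort,
    write_cohort,
)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "brainstates_run"
    sim: dict = field(default_factory=dict)
    drop_n: int = 5
    band: tuple[float, float] | None = None
    # generator output is already standardized; per-run re-standardization
    # is state-dependent when a run expresses few states (rest), which
    # breaks the shared emission model
    zscore: bool = False
    k: int = 10
    restarts: int = 3
    max_iter: int = 200
    n_perm: int = 5000
    nbs_primary_t: float = 2.5
    seed: int = 0
    window_volumes: int = 9

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        band = raw.get("band")
        if band is not None:
            raw["band"] = (float(band[0]), float(band[1]))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["band"] is not None:
            d["band"] = list(d["band"])
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _echo_config(config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    payload = config.to_dict()
    payload["config_hash"] = config.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def stage_simulate(config: RunConfig) -> Path:
    """Generate the cohort, annotations, physiology and questionnaire."""
    out = Path(config.out_dir)
    _echo_config(config, out)
    sim_cfg = SimConfig(**{**config.sim, "seed": config.sim.get(
        "seed", config.seed)})
    runs, truth = generate_cohort(sim_cfg)
    # keep only category->state assignments representable at this K
    category_map = {
        cat: kept
        for cat, states in DEFAULT_CATEGORY_MAP.items()
        if (kept := tuple(s for s in states if s <= sim_cfg.K_true))
    }
    annotations = attach_annotations(truth, category_map)
    physio = attach_physio(truth, seed=sim_cfg.seed + 101)
    questionnaire = attach_questionnaire(truth)
    write_cohort(out / "cohort", runs, truth, annotations, physio,
                 questionnaire)
    return out / "cohort"


def _iter_cohort_runs(cohort_dir: Path):
    for path in sorted((cohort_dir / "runs").glob("*.tsv")):
        yield read_run(path)


def stage_preprocess(config: RunConfig) -> Path:
    """Apply drop/filter/z-score to every run of the cohort."""
    out = Path(config.out_dir)
    prep_dir = out / "prepared"
    prov = {}
    for run in _iter_cohort_runs(out / "cohort"):
        prepared = prepare_run(run, drop_n=config.drop_n, band=config.band,
                               zscore=config.zscore)
        name = f"{run.subject_id}_ses-{run.session}_{run.condition}.tsv"
        write_run(prepared.run, prep_dir / name)
        prov[name] = prepared.provenance.to_dict()
    (prep_dir / "provenance.json").write_text(
        json.dumps({**_stamp(config), "runs": prov}, indent=1)
    )
    return prep_dir


def _load_prepared(config: RunConfig) -> list[PreparedRun]:
    prep_dir = Path(config.out_dir) / "prepared"
    runs = []
    for path in sorted(prep_dir.glob("*.tsv")):
        runs.append(read_run(path))
    return runs


def stage_fit(config: RunConfig) -> Path:
    """Concatenate prepared runs and fit the K-state HMM."""
    out = Path(config.out_dir)
    data = concatenate(_load_prepared(config))
    fit = fit_hmm(data, K=config.k, restarts=config.restarts,
                  max_iter=config.max_iter, seed=config.seed)
    payload = fit.params.to_dict()
    payload.update(_stamp(config))
    payload["loglik"] = fit.loglik
    payload["aic"] = fit.aic
    payload["converged"] = fit.converged
    payload["n_iter"] = fit.n_iter
    payload["concat_shape"] = list(data.values.shape)
    (out / "params.json").write_text(json.dumps(payload))
    return out / "params.json"


def stage_decode(config: RunConfig) -> Path:
    """Viterbi-decode every run under the fitted model."""
    out = Path(config.out_dir)
    params = HMMParams.from_dict(
        json.loads((out / "params.json").read_text())
    )
    data = concatenate(_load_prepared(config))
    decoding = decode(params, data)
    rows = []
    for seg, path in zip(decoding.segments, decoding.paths):
        for t, s in enumerate(path):
            rows.append((seg.subject_id, seg.session, seg.condition, t, s))
    df = pd.DataFrame(
        rows, columns=["subject", "session", "condition", "time_index",
                       "state"]
    )
    df.to_csv(out / "paths.tsv", sep="\t", index=False)
    return out / "paths.tsv"


def load_paths(config: RunConfig) -> dict:
    """(subject, session, condition) -> 1-based decoded path."""
    df = pd.read_csv(Path(config.out_dir) / "paths.tsv", sep="\t")
    out = {}
    for key, grp in df.groupby(["subject", "session", "condition"]):
        out[tuple(key)] = grp.sort_values("time_index")["state"].to_numpy()
    return out


def _tr_seconds(config: RunConfig) -> float:
    cfg = yaml.safe_load(
        (Path(config.out_dir) / "cohort" / "config.yaml").read_text()
    )
    return float(cfg["tr_seconds"])


def stage_dynamics(config: RunConfig) -> Path:
    """FO/dwell/transition summaries and rest-vs-movie contrasts."""
    out = Path(config.out_dir)
    paths = load_paths(config)
    K = config.k
    tr = _tr_seconds(config)
    table = dyn.summarize_dynamics(paths, tr, K)
    table.to_csv(out / "dynamics.tsv", sep="\t", index=False)

    fo_contrast = dyn.paired_state_contrast(table, value="fo")
    dwell_contrast = dyn.paired_state_contrast(table, value="mean_dwell_s")

    subjects = sorted({k[0] for k in paths})
    sessions = sorted({k[1] for k in paths})

    def subject_mats(cond):
        mats = []
        for sub in subjects:
            per_ses = [dyn.empirical_transitions(paths[(sub, ses, cond)], K)
                       for ses in sessions]
            mats.append(np.nanmean(per_ses, axis=0))
        return np.array(mats)

    movie_mats = subject_mats("movie")
    rest_mats = subject_mats("rest")
    nbs = dyn.nbs_transition_contrast(
        movie_mats, rest_mats, primary_t=config.nbs_primary_t,
        n_perm=config.n_perm, seed=config.seed + 11,
    )
    top_movie = dyn.threshold_transitions(np.nanmean(movie_mats, axis=0))
    top_rest = dyn.threshold_transitions(np.nanmean(rest_mats, axis=0))
    result = {
        **_stamp(config),
        "fo_contrast": fo_contrast.to_dict(orient="records"),
        "dwell_contrast": dwell_contrast.to_dict(orient="records"),
        "top_transitions": {"movie": top_movie, "rest": top_rest},
        "nbs": {
            "primary_t": nbs.primary_t,
            "n_perm": nbs.n_perm,
            "movie_gt_rest": [
                {"edges": c.edges, "size": c.size, "p_fwe": c.p_fwe}
                for c in nbs.components_a_gt_b
            ],
            "rest_gt_movie": [
                {"edges": c.edges, "size": c.size, "p_fwe": c.p_fwe}
                for c in nbs.components_b_gt_a
            ],
        },
    }
    (out / "dynamics_contrasts.json").write_text(json.dumps(result, indent=1))
    return out / "dynamics_contrasts.json"


def stage_consistency(config: RunConfig) -> Path:
    """Sliding-window consistency traces and cross-session Jaccard."""
    out = Path(config.out_dir)
    paths = load_paths(config)
    K = config.k
    subjects = sorted({k[0] for k in paths})
    sessions = sorted({k[1] for k in paths})
    traces = []
    for cond in ("rest", "movie"):
        for ses in sessions:
            P = np.array([paths[(sub, ses, cond)] for sub in subjects])
            percent, modal = cons.sliding_consistency(
                P, K, window_volumes=config.window_volumes
            )
            for t in range(P.shape[1]):
                traces.append((cond, ses, t, percent[t], modal[t]))
    pd.DataFrame(
        traces,
        columns=["condition", "session", "time_index", "percent",
                 "modal_state"],
    ).to_csv(out / "consistency_traces.tsv", sep="\t", index=False)

    result: dict = dict(_stamp(config))
    if len(sessions) >= 2:
        jac = {}
        for cond in ("rest", "movie"):
            jac[cond] = [
                cons.cross_session_jaccard(
                    paths[(sub, sessions[0], cond)],
                    paths[(sub, sessions[1], cond)], K,
                )[1]
                for sub in subjects
            ]
        t, p, dof = cons.consistency_contrast(
            np.array(jac["movie"]), np.array(jac["rest"])
        )
        result.update(
            mean_jaccard_movie=float(np.mean(jac["movie"])),
            mean_jaccard_rest=float(np.mean(jac["rest"])),
            per_subject_jaccard=jac, t=t, p=p, df=dof,
        )
    (out / "consistency.json").write_text(json.dumps(result, indent=1))
    return out / "consistency.json"


def stage_coupling(config: RunConfig) -> Path:
    """State-annotation overlap statistics and physiological deviations."""
    out = Path(config.out_dir)
    paths = load_paths(config)
    K = config.k
    tr = _tr_seconds(config)
    drop = config.drop_n
    subjects = sorted({k[0] for k in paths})
    session = sorted({k[1] for k in paths})[0]
    movie_paths = {sub: paths[(sub, session, "movie")] for sub in subjects}
    T_full = len(next(iter(movie_paths.values()))) + drop

    ann = pd.read_csv(out / "cohort" / "annotations.tsv", sep="\t")
    tracks = {}
    for category, grp in ann.groupby("category"):
        track = coup.binarize_annotations(
            grp[["onset_s", "offset_s"]].to_numpy(), tr, T_full
        )
        tracks[category] = track[drop:]
    overlap = coup.overlap_family_test(
        movie_paths, tracks, K, n_perm=config.n_perm, seed=config.seed + 23
    )
    overlap.to_csv(out / "coupling_overlap.tsv", sep="\t", index=False)

    physio_dir = out / "cohort" / "physio"
    deltas = {"hr": [], "pd": []}
    lum_r = []
    for sub in subjects:
        path = movie_paths[sub]
        for kind in ("hr", "pd"):
            f = physio_dir / f"{sub}_ses-{session}_{kind}.tsv"
            trace = pd.read_csv(f, sep="\t")["value"].to_numpy()[drop:]
            deltas[kind].append(
                coup.physio_state_deviation(trace, path, K)
            )
        pd_trace = pd.read_csv(
            physio_dir / f"{sub}_ses-{session}_pd.tsv", sep="\t"
        )["value"].to_numpy()[drop:]
        lum = pd.read_csv(
            physio_dir / f"{sub}_ses-{session}_luminance.tsv", sep="\t"
        )["value"].to_numpy()[drop:]
        if lum.std() > 0:
            lum_r.append(coup.correlate_traces(pd_trace, lum)[0])
    hr_test = coup.group_physio_test(np.array(deltas["hr"]))
    pd_test = coup.group_physio_test(np.array(deltas["pd"]))
    result = {
        **_stamp(config),
        "hr_deviation": hr_test.to_dict(orient="records"),
        "pd_deviation": pd_test.to_dict(orient="records"),
        "pd_luminance_r_mean": float(np.mean(lum_r)) if lum_r else None,
        "fwe_threshold": coup.fwe_threshold(0.05, K, len(tracks)),
    }
    (out / "coupling_physio.json").write_text(json.dumps(result, indent=1))
    return out / "coupling_physio.json"


def stage_isrsa(config: RunConfig) -> Path:
    """Distance representations, MDS embedding and Mantel tests."""
    out = Path(config.out_dir)
    paths = load_paths(config)
    K = config.k
    subjects = sorted({k[0] for k in paths})
    session = sorted({k[1] for k in paths})[0]

    ratings = pd.read_csv(out / "cohort" / "questionnaire.csv")
    ratings = ratings.set_index("subject_id").loc[subjects]
    D_q = isrsa.questionnaire_distance(ratings.to_numpy())

    fo = np.array([
        dyn.fractional_occupancy(paths[(sub, session, "movie")], K)
        for sub in subjects
    ])
    mats = np.array([
        dyn.empirical_transitions(paths[(sub, session, "movie")], K)
        for sub in subjects
    ])
    movie_P = np.array([paths[(sub, session, "movie")] for sub in subjects])

    D_fo = isrsa.fo_distance(fo)
    D_tr = isrsa.transition_distance(mats)
    D_path = isrsa.path_distance_matrix(movie_P, K)

    results = {}
    for name, D in (("fo", D_fo), ("transitions", D_tr), ("path", D_path)):
        m = isrsa.mantel_correlation(D, D_q, n_perm=config.n_perm,
                                     seed=config.seed + 31)
        results[name] = dict(r=m.r, z=m.z, p=m.p, n_perm=m.n_perm)
        pd.DataFrame(D, index=subjects, columns=subjects).to_csv(
            out / f"distance_{name}.tsv", sep="\t"
        )
    pd.DataFrame(D_q, index=subjects, columns=subjects).to_csv(
        out / "distance_questionnaire.tsv", sep="\t"
    )

    emb = isrsa.classical_mds(D_q, dims=2)
    pd.DataFrame(
        emb.coordinates, index=subjects, columns=["dim1", "dim2"]
    ).to_csv(out / "mds_questionnaire.tsv", sep="\t")

    (out / "isrsa.json").write_text(
        json.dumps({**_stamp(config), "mantel": results}, indent=1)
    )
    return out / "isrsa.json"


def stage_report(config: RunConfig) -> Path:
    """Collect stage outputs into one summary JSON and a markdown report."""
    out = Path(config.out_dir)
    summary: dict = dict(_stamp(config))
    params = json.loads((out / "params.json").read_text())
    summary["concat_shape"] = params["concat_shape"]
    summary["loglik"] = params["loglik"]
    summary["aic"] = params["aic"]
    for name in ("consistency", "isrsa", "coupling_physio",
                 "dynamics_contrasts"):
        f = out / f"{name}.json"
        if f.exists():
            summary[name] = json.loads(f.read_text())
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    lines = [
        "# Brain-state dynamics report",
        f"config hash: {config.config_hash()}  seed: {config.seed}",
        f"concatenated matrix: {params['concat_shape'][0]} x "
        f"{params['concat_shape'][1]}",
        f"K = {config.k}, log-likelihood {params['loglik']:.1f}, "
        f"AIC {params['aic']:.1f}",
    ]
    consf = out / "consistency.json"
    if consf.exists():
        c = json.loads(consf.read_text())
        if "mean_jaccard_movie" in c:
            lines.append(
                f"cross-session Jaccard: movie "
                f"{c['mean_jaccard_movie']:.3f}, rest "
                f"{c['mean_jaccard_rest']:.3f} (paired t={c['t']:.2f}, "
                f"p={c['p']:.2g})"
            )
    (out / "report.md").write_text("\n\n".join(lines) + "\n")
    return out / "summary.json"


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit": stage_fit,
    "decode": stage_decode,
    "dynamics": stage_dynamics,
    "consistency": stage_consistency,
    "coupling": stage_coupling,
    "isrsa": stage_isrsa,
    "report": stage_report,
}

STAGE_ORDER = list(_STAGES)


def run_stage(name: str, config: RunConfig) -> Path:
    try:
        stage = _STAGES[name]
    except KeyError:
        raise ValueError(f"unknown stage {name!r}") from None
    try:
        return stage(config)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the artifact directory."""
    for name in STAGE_ORDER:
        run_stage(name, config)
    return Path(config.out_dir)
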