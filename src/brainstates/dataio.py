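"""Reading, writing and temporal preprocessing of network fMRI time series.

Each run is a T x D table of network-averaged BOLD values (one column per
canonical brain network, one row per TR).  Runs are stored as TSV with a
JSON sidecar carrying the metadata (subject, session, condition,
tr_seconds).  Temporal preprocessing follows a fixed stage order:
drop initial volumes -> band-pass filter -> confound regression -> z-score,
with every stage recorded in the run's provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal


class ParseError(ValueError):
    """Raised when a run table cannot be parsed; message names the offending cell."""


@dataclass
class RunTimeSeries:
    """One scanning run reduced to network-averaged time series (T x D)."""

    subject_id: str
    session: str
    condition: str
    tr_seconds: float
    network_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        T, D = self.values.shape
        if T < 1:
            raise ValueError("run must contain at least one timepoint")
        if len(self.network_labels) != D:
            raise ValueError(
                f"{len(self.network_labels)} labels for {D} columns"
            )
        if len(set(self.network_labels)) != D:
            raise ValueError("network labels must be unique")
        if not np.all(np.isfinite(self.values)):
            t, d = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {t}, network {self.network_labels[d]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]

    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.session, self.condition)


@dataclass
class Provenance:
    volumes_dropped: int = 0
    filtered: bool = False
    band_hz: tuple[float, float] | None = None
    confounds_regressed: bool = False
    zscored: bool = False

    def to_dict(self) -> dict:
        return {
            "volumes_dropped": self.volumes_dropped,
            "filtered": self.filtered,
            "band_hz": list(self.band_hz) if self.band_hz else None,
            "confounds_regressed": self.confounds_regressed,
            "zscored": self.zscored,
        }


@dataclass
class PreparedRun:
    """A RunTimeSeries after temporal preprocessing, with stage provenance."""

    run: RunTimeSeries
    provenance: Provenance

    @property
    def values(self) -> np.ndarray:
        return self.run.values

    @property
    def network_labels(self) -> list[str]:
        return self.run.network_labels

    def key(self) -> tuple[str, str, str]:
        return self.run.key()


@dataclass(frozen=True)
class Segment:
    """Location of one run inside a concatenated matrix."""

    subject_id: str
    session: str
    condition: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class ConcatDataset:
    """Stacked multi-run observation matrix with a segment index.

    ``segments`` tile the N rows contiguously and without overlap; the HMM
    treats each segment as an independent observation sequence.
    """

    values: np.ndarray
    segments: list[Segment]
    network_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError("segments must tile rows contiguously")
            pos = seg.stop
        if pos != self.values.shape[0]:
            raise ValueError("segments do not cover all rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def segment_values(self, seg: Segment) -> np.ndarray:
        return self.values[seg.slice]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_run(run: RunTimeSeries, path: str | Path) -> None:
    """Write a run as TSV (header = network labels) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(run.values, columns=run.network_labels)
    # repr-based formatting preserves float64 round-trip exactly
    df.to_csv(path, sep="\t", index=False, float_format=None)
    meta = {
        "subject_id": run.subject_id,
        "session": run.session,
        "condition": run.condition,
        "tr_seconds": run.tr_seconds,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_run(path: str | Path) -> RunTimeSeries:
    """Read a TSV run table and its JSON sidecar back into a RunTimeSeries."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(
                    f"{path.name}: line {lineno} has {len(cells)} cells, "
                    f"expected {len(header)}"
                )
            row = []
            for col, cell in zip(header, cells):
                try:
                    value = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}: non-numeric cell at line {lineno}, "
                        f"column {col}: {cell!r}"
                    ) from None
                if not np.isfinite(value):
                    raise ParseError(
                        f"{path.name}: non-finite value at line {lineno}, column {col}"
                    )
                row.append(value)
            rows.append(row)
    if len(set(header)) != len(header):
        raise ParseError(f"{path.name}: duplicate network labels in header")
    meta = json.loads(_sidecar_path(path).read_text())
    return RunTimeSeries(
        subject_id=meta["subject_id"],
        session=meta["session"],
        condition=meta["condition"],
        tr_seconds=float(meta["tr_seconds"]),
        network_labels=header,
        values=np.array(rows, dtype=float),
    )


def bandpass_filter(values: np.ndarray, band_hz: tuple[float, float],
                    tr_seconds: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, applied per column."""
    fs = 1.0 / tr_seconds
    low, high = band_hz
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie strictly inside (0, {nyq:.4g}) Hz"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, values, axis=0)


def regress_confounds(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of each column on the confounds (intercept included)."""
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != values.shape[0]:
        raise ValueError("confound matrix length does not match run length")
    X = np.column_stack([np.ones(len(values)), confounds])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def zscore_columns(values: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Scale each column to zero mean, unit (population) SD."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"constant column cannot be z-scored: network {labels[bad[0]]}"
        )
    return (values - mu) / sd


def prepare_run(
    run: RunTimeSeries,
    drop_n: int = 5,
    band: tuple[float, float] | None = (0.01, 0.15),
    confounds: np.ndarray | None = None,
    zscore: bool = True,
) -> PreparedRun:
    """Temporal preprocessing: drop -> band-pass -> confound OLS -> z-score.

    ``confounds`` is given at the original run length and trimmed together
    with the data.  Stage order is fixed; each executed stage is recorded.
    """
    if drop_n < 0 or drop_n >= run.n_timepoints:
        raise ValueError("drop_n must satisfy 0 <= drop_n < T")
    values = run.values[drop_n:].copy()
    prov = Provenance(volumes_dropped=drop_n)
    if band is not None:
        values = bandpass_filter(values, band, run.tr_seconds)
        prov.filtered = True
        prov.band_hz = (float(band[0]), float(band[1]))
    if confounds is not None:
        conf = np.asarray(confounds, dtype=float)
        if conf.shape[0] == run.n_timepoints:
            conf = conf[drop_n:]
        values = regress_confounds(values, conf)
        prov.confounds_regressed = True
    if zscore:
        values = zscore_columns(values, run.network_labels)
        prov.zscored = True
    out = RunTimeSeries(
        subject_id=run.subject_id,
        session=run.session,
        condition=run.condition,
        tr_seconds=run.tr_seconds,
        network_labels=list(run.network_labels),
        values=values,
    )
    return PreparedRun(run=out, provenance=prov)


def concatenate(runs: Sequence[PreparedRun | RunTimeSeries]) -> ConcatDataset:
    """Stack runs row-wise into one observation matrix with a segment index."""
    if not runs:
        raise ValueError("no runs to concatenate")
    base = runs[0].network_labels
    blocks, segments, pos = [], [], 0
    for r in runs:
        inner = r.run if isinstance(r, PreparedRun) else r
        if list(r.network_labels) != list(base):
            raise ValueError(
                f"network label order mismatch in run "
                f"{inner.subject_id}/{inner.session}/{inner.condition}"
            )
        T = inner.values.shape[0]
        segments.append(
            Segment(inner.subject_id, inner.session, inner.condition, pos, T)
        )
        blocks.append(inner.values)
        pos += T
    return ConcatDataset(
        values=np.vstack(blocks), segments=segments, network_labels=list(base)
    )
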