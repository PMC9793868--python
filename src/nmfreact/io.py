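"""Reading and writing the pipeline's domain objects.

Trace matrices travel as delimited text (CSV with ``#``-prefixed metadata
lines and a neuron-id header row) or as HDF5 datasets with the same metadata
in attributes; ensembles, ground truth and reports as JSON; event counts and
rank tables as CSV.  Write-then-read round trips are lossless at full float
precision.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extract import EnsembleSet, RankSelectionTable
from .preprocess import (BinnedMatrix, EventCounts, FluorescenceMatrix,
                         STAGES, TraceMatrix)
from .synthetic import GroundTruthEnsembles, GroundTruthSession, SimulationParams

_MAGIC = "# nmfreact-traces v1"


class TraceParseError(ValueError):
    """Malformed trace file; message carries the offending line/row."""


# ---------------------------------------------------------------------------
# trace matrices — delimited text


def write_traces_csv(traces: FluorescenceMatrix | TraceMatrix, path) -> None:
    path = Path(path)
    stage = getattr(traces, "stage", "raw")
    with path.open("w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"# session_id: {traces.session_id}\n")
        fh.write(f"# frame_rate: {traces.frame_rate!r}\n")
        fh.write(f"# stage: {stage}\n")
        fh.write(",".join(str(int(i)) for i in traces.neuron_ids) + "\n")
        np.savetxt(fh, traces.values, delimiter=",", fmt="%.17g")


def read_traces_csv(path) -> FluorescenceMatrix | TraceMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    else:
        raise TraceParseError(f"{path}: no data rows found")
    for key in ("frame_rate", "stage"):
        if key not in meta:
            raise TraceParseError(f"{path}: missing metadata line '# {key}: ...'")

    try:
        df = pd.read_csv(_stdio.StringIO("".join(lines[body_start:])),
                         float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise TraceParseError(f"{path}: malformed delimited text: {err}") from err
    if df.shape[0] == 0:
        raise TraceParseError(f"{path}: no data rows found")
    try:
        neuron_ids = np.array([int(c) for c in df.columns])
    except ValueError as err:
        raise TraceParseError(f"{path}: header must hold integer neuron ids: {err}") from err

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise TraceParseError(
                f"{path}: non-numeric cell at data row {row}, neuron column {col!r}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise TraceParseError(f"{path}: missing value at data row {row}, column {col!r}")
        values[:, j] = numeric.to_numpy()

    frame_rate = float(meta["frame_rate"])
    session_id = meta.get("session_id", "")
    stage = meta["stage"]
    if stage == "raw":
        return FluorescenceMatrix(values, frame_rate=frame_rate,
                                  session_id=session_id, neuron_ids=neuron_ids)
    if stage not in STAGES:
        raise TraceParseError(f"{path}: unknown stage {stage!r}")
    return TraceMatrix(values, stage=stage, frame_rate=frame_rate,
                       session_id=session_id, neuron_ids=neuron_ids)


# ---------------------------------------------------------------------------
# trace matrices — HDF5


def write_traces_h5(traces: FluorescenceMatrix | TraceMatrix, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=traces.values)
        ds.attrs["session_id"] = traces.session_id
        ds.attrs["frame_rate"] = traces.frame_rate
        ds.attrs["stage"] = getattr(traces, "stage", "raw")
        fh.create_dataset("neuron_ids", data=np.asarray(traces.neuron_ids, dtype=int))


def read_traces_h5(path) -> FluorescenceMatrix | TraceMatrix:
    with h5py.File(path, "r") as fh:
        ds = fh["values"]
        values = ds[()]
        stage = ds.attrs["stage"]
        frame_rate = float(ds.attrs["frame_rate"])
        session_id = str(ds.attrs["session_id"])
        neuron_ids = fh["neuron_ids"][()]
    if stage == "raw":
        return FluorescenceMatrix(values, frame_rate=frame_rate,
                                  session_id=session_id, neuron_ids=neuron_ids)
    return TraceMatrix(values, stage=stage, frame_rate=frame_rate,
                       session_id=session_id, neuron_ids=neuron_ids)


def read_trace_matrix(path, fmt: str | None = None):
    """Dispatch on extension (.csv/.h5) unless ``fmt`` is given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    fmt = fmt or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    return read_traces_h5(path) if fmt == "h5" else read_traces_csv(path)


def write_trace_matrix(traces, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    (write_traces_h5 if fmt == "h5" else write_traces_csv)(traces, path)


# ---------------------------------------------------------------------------
# ensembles, ground truth, tables


def write_ensembles_json(ens: EnsembleSet, path) -> None:
    doc = {
        "session_id": ens.session_id,
        "n_ensembles": int(ens.n_ensembles),
        "cost": float(ens.cost),
        "neuron_ids": ens.neuron_ids.tolist(),
        "patterns": ens.patterns.tolist(),
        "occurrences": ens.occurrences.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_ensembles_json(path) -> EnsembleSet:
    doc = json.loads(Path(path).read_text())
    patterns = np.asarray(doc["patterns"], dtype=float)
    return EnsembleSet(patterns=patterns,
                       occurrences=np.asarray(doc["occurrences"], dtype=float),
                       n_ensembles=int(doc["n_ensembles"]),
                       session_id=doc["session_id"], cost=float(doc["cost"]),
                       neuron_ids=np.asarray(doc["neuron_ids"], dtype=int))


def write_ground_truth_json(session: GroundTruthSession, path,
                            shared_map: dict | None = None) -> None:
    from dataclasses import asdict

    doc = {
        "params": asdict(session.params),
        "membership": session.ensembles.membership.tolist(),
        "neuron_ids": session.ensembles.neuron_ids.tolist(),
        "occurrence_times": [t.tolist() for t in session.occurrence_times],
        "shared_map": {str(k): int(v) for k, v in (shared_map or {}).items()},
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth_json(path):
    doc = json.loads(Path(path).read_text())
    gt = GroundTruthEnsembles(np.asarray(doc["membership"], dtype=float),
                              np.asarray(doc["neuron_ids"], dtype=int))
    params = SimulationParams(**doc["params"])
    occ = [np.asarray(t, dtype=int) for t in doc["occurrence_times"]]
    shared_map = {int(k): int(v) for k, v in doc["shared_map"].items()}
    return gt, params, occ, shared_map


def write_rank_table_csv(table: RankSelectionTable, path) -> None:
    pd.DataFrame({"rank": table.candidate_ranks, "aicc": table.aicc,
                  "rss": table.rss}).to_csv(path, index=False)


def write_event_counts_csv(counts: EventCounts, path) -> None:
    pd.DataFrame({"neuron_id": counts.neuron_ids,
                  "n_events": counts.per_neuron}).to_csv(path, index=False)


def write_similarity_csv(values: np.ndarray, path) -> None:
    pd.DataFrame(values).to_csv(path, index=False, header=False)


def plot_similarity_heatmap(values: np.ndarray, path, session_x: str = "X",
                            session_y: str = "Y") -> None:
    """Similarity heat map (patterns of X on the vertical axis) to a raster file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values, vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xlabel(f"patterns in {session_y}")
    ax.set_ylabel(f"patterns in {session_x}")
    fig.colorbar(im, ax=ax, label="cosine similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
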