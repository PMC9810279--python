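"""Plain-text serialization: TSV matrices with JSON sidecars.

File conventions
----------------
* time series       ``<sub>_timeseries.tsv`` (T x N, tab-separated, header =
  node labels) + ``<sub>_timeseries.json`` sidecar (tr_seconds, subject_id)
* confounds         ``<sub>_confounds.tsv`` with fMRIPrep-dialect columns
  (trans_x..rot_z, white_matter, csf, global_signal)
* scores            ``scores.csv`` (one row per subject)
* ground truth      ``<sub>_truth.json``
* partitions        ``<sub>_partition.tsv`` (L x N integer labels) + JSON
  metadata (gamma, omega, n_runs, seed, q_value)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .multilayer import MultilayerPartition
from .preprocess import MotionTrace, ParcellatedTimeSeries
from .synthetic import SyntheticGroundTruth

FMRIPREP_MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_timeseries(series: ParcellatedTimeSeries, directory: Path, stem: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or series.subject_id or "sub"
    path = directory / f"{stem}_timeseries.tsv"
    pd.DataFrame(series.values, columns=series.node_labels).to_csv(path, sep="\t", index=False)
    sidecar = {
        "tr_seconds": series.tr_seconds,
        "subject_id": series.subject_id,
        "node_labels": series.node_labels,
        "provenance": series.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_timeseries(path: Path) -> ParcellatedTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return ParcellatedTimeSeries(
        values=df.to_numpy(dtype=float),
        tr_seconds=float(meta["tr_seconds"]),
        node_labels=list(df.columns),
        subject_id=meta.get("subject_id", path.stem),
        provenance=list(meta.get("provenance", [])),
    )


def write_confounds(
    motion: MotionTrace,
    directory: Path,
    stem: str,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    gs: np.ndarray | None = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = dict(zip(FMRIPREP_MOTION_COLUMNS, motion.as_matrix().T))
    T = motion.n_volumes
    data["white_matter"] = np.zeros(T) if wm is None else np.asarray(wm, float)
    data["csf"] = np.zeros(T) if csf is None else np.asarray(csf, float)
    data["global_signal"] = np.zeros(T) if gs is None else np.asarray(gs, float)
    path = directory / f"{stem}_confounds.tsv"
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    return path


def read_confounds(path: Path, tr_seconds: float) -> tuple[MotionTrace, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FMRIPREP_MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"confound table {path} lacks columns {missing}")
    trace = MotionTrace(
        translations=df[FMRIPREP_MOTION_COLUMNS[:3]].to_numpy(float),
        rotations=df[FMRIPREP_MOTION_COLUMNS[3:]].to_numpy(float),
        tr_seconds=tr_seconds,
    )
    return trace, df


def write_ground_truth(truth: SyntheticGroundTruth, directory: Path, stem: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "community_assignment": truth.community_assignment.tolist(),
        "epoch_starts": truth.epoch_starts.tolist(),
        "switching_nodes": sorted(truth.switching_nodes),
        "dynamic_edges": sorted(truth.dynamic_edges),
        "planted_metric": truth.planted_metric,
        "subject_seed": truth.subject_seed,
    }
    path = directory / f"{stem}_truth.json"
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: Path) -> SyntheticGroundTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        community_assignment=np.asarray(d["community_assignment"], dtype=int),
        epoch_starts=np.asarray(d["epoch_starts"], dtype=int),
        switching_nodes=set(d["switching_nodes"]),
        dynamic_edges={tuple(e) for e in d["dynamic_edges"]},
        planted_metric=float(d["planted_metric"]),
        subject_seed=int(d["subject_seed"]),
    )


def write_partition(
    partition: MultilayerPartition, directory: Path, stem: str,
    gamma: float = 1.0, omega: float = 1.0,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}_partition.tsv"
    np.savetxt(path, partition.labels, fmt="%d", delimiter="\t")
    meta = {
        "q_value": partition.q_value,
        "n_runs": partition.n_runs,
        "best_run_index": partition.best_run_index,
        "seed": partition.seed,
        "gamma": gamma,
        "omega": omega,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_partition(path: Path) -> MultilayerPartition:
    path = Path(path)
    labels = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MultilayerPartition(
        labels=labels,
        q_value=float(meta["q_value"]),
        n_runs=int(meta["n_runs"]),
        best_run_index=int(meta["best_run_index"]),
        seed=int(meta["seed"]),
    )
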