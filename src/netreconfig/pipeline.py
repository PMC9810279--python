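"""End-to-end orchestration of the reconfiguration pipeline.

A run takes a cohort directory (per-subject time series + confounds, a
scores table, and an atlas node->RSN mapping), executes

    preprocess -> windowed connectivity -> surrogate degree test
               -> multilayer modularity -> flexibility/promiscuity
               -> aggregation -> brain-behavior correlation grid

and persists every intermediate together with a manifest (config hash,
seeds, per-file checksums) so identical configurations reproduce identical
outputs bit for bit.

Two named modes mirror the two study pipelines:

* ``replication`` — lenient 26-parameter denoising, decimation by 3 to a
  virtual TR, 20-sample nonoverlapping windows;
* ``native``      — 36-parameter denoising, full temporal resolution,
  148-sample overlapping windows advanced by 1 TR.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .multilayer import best_of_runs, flexibility, prepare_layers, promiscuity
from .preprocess import (
    build_confound_model,
    compute_fd,
    downsample,
    filter_motion_trace,
    qc_exclude,
    regress_confounds,
)
from .stats import aggregate, correlation_grid
from .synthetic import SyntheticConfig, generate_bold, generate_motion, generate_scores
from .tvfc import WindowSpec, node_degree, surrogate_test, windowed_correlation

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3

MODE_PRESETS = {
    "replication": {
        "confound_model": "26-parameter",
        "downsample_factor": 3,
        "window": {"length_samples": 20, "scheme": "nonoverlapping"},
    },
    "native": {
        "confound_model": "36-parameter",
        "downsample_factor": 1,
        "window": {"length_samples": 148, "step_samples": 1, "scheme": "overlapping"},
    },
}


class PipelineError(RuntimeError):
    """A stage failure carrying stage name, subject and cause."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs, resolvable from YAML."""

    mode: str = "custom"
    confound_model: str = "36-parameter"
    downsample_factor: int = 1
    window: dict = field(default_factory=lambda: {"length_samples": 148, "step_samples": 1,
                                                  "taper": "hamming", "scheme": "overlapping"})
    passband_hz: tuple[float, float] = (0.01, 0.08)
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 100
    n_surrogates: int = 500
    fdr_alpha: float = 0.05
    seed: int = 0
    apply_qc: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("custom", *MODE_PRESETS):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in MODE_PRESETS:
            preset = MODE_PRESETS[self.mode]
            self.confound_model = preset["confound_model"]
            self.downsample_factor = preset["downsample_factor"]
            self.window = {**self.window, **preset["window"]}
        self.passband_hz = tuple(self.passband_hz)  # type: ignore[assignment]

    def window_spec(self) -> WindowSpec:
        return WindowSpec(**self.window)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed: adding subjects never perturbs existing ones."""
    digest = hashlib.sha256(f"{master_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Single-subject processing
# ---------------------------------------------------------------------------

def process_subject(
    series, motion, confound_table: pd.DataFrame, config: PipelineConfig,
    compute_degree: bool = True,
) -> dict:
    """Run one subject through preprocess -> TVFC -> multilayer -> metrics.

    Returns a dict with the QC decision, mean-FD covariate, node metric
    vectors, nodal-degree percentages, and the partition.
    """
    sid = series.subject_id
    seed = subject_seed(config.seed, sid)
    out: dict = {"subject_id": sid}

    try:  # --- motion QC -------------------------------------------------
        fd_raw = compute_fd(motion)
        filtered = filter_motion_trace(motion)
        fd_filt = compute_fd(filtered)
        decision = qc_exclude(fd_filt)
        out["qc"] = decision
        out["mean_fd_filt"] = float(fd_filt.mean())
        out["mean_fd_raw"] = float(fd_raw.mean())
    except Exception as err:
        raise PipelineError("motion-qc", sid, err) from err

    try:  # --- denoising -------------------------------------------------
        wm = confound_table.get("white_matter", pd.Series(np.zeros(series.n_volumes))).to_numpy(float)
        csf = confound_table.get("csf", pd.Series(np.zeros(series.n_volumes))).to_numpy(float)
        gs = confound_table.get("global_signal", pd.Series(np.zeros(series.n_volumes))).to_numpy(float)
        confounds = build_confound_model(motion, wm, csf, gs, model=config.confound_model)
        clean = regress_confounds(series, confounds, passband=config.passband_hz)
    except Exception as err:
        raise PipelineError("preprocess", sid, err) from err

    try:  # --- down-sampling ---------------------------------------------
        if config.downsample_factor > 1:
            clean, motion_ds = downsample(clean, config.downsample_factor, motion)
            # at the reduced rate FD is computed without filtering
            out["mean_fd_covariate"] = float(compute_fd(motion_ds).mean())
        else:
            out["mean_fd_covariate"] = out["mean_fd_filt"]
    except Exception as err:
        raise PipelineError("downsample", sid, err) from err

    try:  # --- TVFC + degree ---------------------------------------------
        spec = config.window_spec()
        stack = windowed_correlation(clean, spec)
        out["n_windows"] = stack.n_layers
        if compute_degree:
            dyn = surrogate_test(
                clean, spec, n_surrogates=config.n_surrogates,
                fdr_alpha=config.fdr_alpha, seed=seed,
            )
            degree, degree_pct = node_degree(dyn, clean.n_nodes)
            out["degree"] = degree
            out["degree_pct"] = degree_pct
            out["edge_dynamics"] = dyn
    except Exception as err:
        raise PipelineError("tvfc", sid, err) from err

    try:  # --- multilayer modularity -------------------------------------
        net = prepare_layers(stack)
        net.gamma, net.omega = config.gamma, config.omega
        partition = best_of_runs(net, n_runs=config.n_runs, seed=seed)
        out["partition"] = partition
        out["flexibility"] = flexibility(partition)
        out["promiscuity"] = promiscuity(partition)
    except Exception as err:
        raise PipelineError("multilayer", sid, err) from err

    return out


# ---------------------------------------------------------------------------
# Cohort-level run
# ---------------------------------------------------------------------------

def _load_cohort(cohort_dir: Path):
    cohort_dir = Path(cohort_dir)
    ts_paths = sorted(cohort_dir.glob("*_timeseries.tsv"))
    if not ts_paths:
        raise FileNotFoundError(f"no *_timeseries.tsv files under {cohort_dir}")
    subjects = []
    for ts_path in ts_paths:
        series = nio.read_timeseries(ts_path)
        stem = ts_path.name.replace("_timeseries.tsv", "")
        conf_path = cohort_dir / f"{stem}_confounds.tsv"
        if not conf_path.exists():
            raise FileNotFoundError(f"missing confounds for subject {stem}: {conf_path}")
        motion, table = nio.read_confounds(conf_path, series.tr_seconds)
        subjects.append((stem, series, motion, table))
    scores = None
    scores_path = cohort_dir / "scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
    mapping = None
    atlas_path = cohort_dir / "atlas.tsv"
    if atlas_path.exists():
        atlas = pd.read_csv(atlas_path, sep="\t")
        mapping = dict(zip(atlas["node"], atlas["rsn"]))
    return subjects, scores, mapping


def _metric_row(result: dict, mapping: dict[str, str] | None, node_labels: list[str]) -> dict:
    row: dict[str, float] = {}
    for metric in ("flexibility", "promiscuity", "degree"):
        vec = result[metric]
        for lab, v in zip(node_labels, vec.values):
            row[f"{metric}__node__{lab}"] = float(v)
        if mapping is not None:
            agg = aggregate(vec, mapping, node_labels)
            for rsn, v in agg.items():
                level = "global" if rsn == "global" else "rsn"
                row[f"{metric}__{level}__{rsn}"] = float(v)
        else:
            row[f"{metric}__global__global"] = float(np.mean(vec.values))
    return row


def run_pipeline(config: PipelineConfig, cohort_dir: Path, out_dir: Path) -> dict:
    """Execute the full pipeline over a cohort directory.

    Writes per-subject partitions and metrics, the cohort metric table, the
    correlation grid (when scores are available) and a run manifest; returns
    the manifest dict.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, scores, mapping = _load_cohort(cohort_dir)

    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {},
        "checksums": {},
        "excluded_subjects": [],
        "warnings": [],
    }

    rows, kept_ids, covar_rows = [], [], []
    for stem, series, motion, table in subjects:
        t_sub = time.time()
        result = process_subject(series, motion, table, config)
        manifest["seeds"][stem] = subject_seed(config.seed, stem)
        if config.apply_qc and result["qc"].excluded:
            manifest["excluded_subjects"].append({"subject": stem, "reason": result["qc"].reason})
            logger.warning("subject %s excluded by motion QC (%s)", stem, result["qc"].reason)
            continue
        p = nio.write_partition(result["partition"], out_dir, stem,
                                gamma=config.gamma, omega=config.omega)
        manifest["checksums"][p.name] = _checksum(p)
        rows.append(_metric_row(result, mapping, series.node_labels))
        covar_rows.append({"subject": stem, "mean_fd": result["mean_fd_covariate"]})
        kept_ids.append(stem)
        logger.info("subject %s done in %.1fs (%d windows)",
                    stem, time.time() - t_sub, result["n_windows"])

    metrics = pd.DataFrame(rows, index=kept_ids)
    metrics_path = out_dir / "metrics.csv"
    metrics.to_csv(metrics_path)
    manifest["checksums"][metrics_path.name] = _checksum(metrics_path)

    if scores is not None and len(kept_ids) >= 8:
        scores = scores.set_index("subject") if "subject" in scores.columns else scores
        scores.index = [str(i) for i in scores.index]
        common = [s for s in kept_ids if s in scores.index]
        score_cols = [c for c in scores.columns if c.endswith("_total")]
        covariates = pd.DataFrame(covar_rows).set_index("subject").loc[common]
        for extra in ("age", "gender"):
            if extra in scores.columns:
                covariates[extra] = scores.loc[common, extra]
        grid = correlation_grid(
            metrics.loc[common],
            scores.loc[common, score_cols],
            covariates,
            alpha=config.fdr_alpha,
        )
        grid_path = out_dir / "correlations.csv"
        grid.to_csv(grid_path, index=False)
        manifest["checksums"][grid_path.name] = _checksum(grid_path)

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixtures(
    seed: int = 0,
    directory: Path = Path("fixtures"),
    n_subjects: int = 5,
    n_nodes: int = 20,
    n_volumes: int = 300,
) -> Path:
    """Write a small synthetic cohort with ground truth for the test suite.

    Half of the switching nodes change community midway through the scan;
    two planted dynamic edges modulate their coupling slowly.  Regeneration
    with the same seed is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    switch_at = n_volumes // 2
    config = SyntheticConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_volumes=n_volumes,
        tr_seconds=2.025,
        n_communities=2,
        switch_schedule=[(i, switch_at, 1) for i in range(0, n_nodes // 4)],
        dynamic_edges=[(0, n_nodes - 1, 0.8), (1, n_nodes - 2, 0.8)],
        dynamic_edge_period=max(2 * 50, n_volumes // 2),
        # low-motion cohort: at this slow TR the respiratory component is
        # aliased near the FD filter cutoff, so keep its amplitude small
        respiratory_amplitude_mm=0.02,
        motion_step_mm=0.01,
        seed=seed,
    )
    truths = []
    for s in range(n_subjects):
        series, truth = generate_bold(config, subject_seed=s)
        motion = generate_motion(config, subject_seed=s)
        stem = series.subject_id
        nio.write_timeseries(series, directory, stem)
        nio.write_confounds(motion, directory, stem)
        nio.write_ground_truth(truth, directory, stem)
        truths.append(truth)
    if n_subjects >= 3:
        scores = generate_scores(truths, coupling=config.score_coupling, seed=seed)
        scores.insert(0, "subject", [f"sub-{s:04d}" for s in range(n_subjects)])
        scores.to_csv(directory / "scores.csv", index=False)
    atlas = pd.DataFrame(
        {
            "node": [f"node_{k:03d}" for k in range(n_nodes)],
            "rsn": [f"rsn_{k % config.n_communities}" for k in range(n_nodes)],
        }
    )
    atlas.to_csv(directory / "atlas.tsv", sep="\t", index=False)
    return directory


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep(
    config: PipelineConfig, cohort_dir: Path, parameter: str, values: list
) -> dict:
    """Re-run the metric stages across values of one parameter.

    ``parameter`` is one of ``window_length``, ``gamma``, ``omega``.  Returns
    a report with group-mean node-flexibility vectors per value and the
    pairwise spatial-similarity (Spearman) matrix between them.
    """
    from .stats import spatial_similarity

    if parameter not in ("window_length", "gamma", "omega"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    if len(values) < 2:
        raise ValueError("need at least 2 sweep values")

    subjects, _, _ = _load_cohort(cohort_dir)
    mean_flex = []
    for value in values:
        cfg_kwargs = asdict(config)
        cfg_kwargs["mode"] = "custom"
        if parameter == "window_length":
            cfg_kwargs["window"] = {**config.window, "length_samples": int(value)}
        else:
            cfg_kwargs[parameter] = float(value)
        cfg = PipelineConfig(**cfg_kwargs)
        flex = []
        for stem, series, motion, table in subjects:
            result = process_subject(series, motion, table, cfg, compute_degree=False)
            flex.append(result["flexibility"].values)
        mean_flex.append(np.mean(flex, axis=0))

    sim = np.ones((len(values), len(values)))
    for a in range(len(values)):
        for b in range(a + 1, len(values)):
            rho, _ = spatial_similarity(mean_flex[a], mean_flex[b])
            sim[a, b] = sim[b, a] = rho
    return {
        "parameter": parameter,
        "values": list(values),
        "mean_flexibility": [v.tolist() for v in mean_flex],
        "spatial_similarity": sim,
    }
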