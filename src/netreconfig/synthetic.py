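"""Synthetic cohorts with known ground truth.

Generates parcellated BOLD-like time series, realignment (motion) traces and
behavioral scores that emulate a fast multiband resting-state acquisition
(defaults: 900 volumes, TR = 0.675 s, 100 nodes, signal power confined to
0.01-0.08 Hz).  Every construct that the analysis pipeline is meant to
recover is planted explicitly:

* modular community structure, with scheduled community switches for
  designated "flexible" nodes,
* edges whose coupling strength varies slowly over the scan ("dynamic"
  edges, detectable as elevated windowed-correlation SD),
* head-motion traces with an optional ~0.3 Hz respiratory component, and
* questionnaire-like scores with a configurable correlation to a chosen
  per-subject network metric.

The community signals are band-limited filtered white noise: the analysis
only ever sees the 0.01-0.08 Hz band, so a generative model beyond matched
frequency content buys nothing for verification purposes.  Switches are
instantaneous label reassignments (no transition ramp), which keeps the
ground truth exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import MotionTrace, ParcellatedTimeSeries

_RNG_PURPOSES = ("signal", "noise", "motion", "scores", "trait")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    snr is the ratio of shared (community) signal variance to node-private
    noise variance; the mixing weight is w = snr / (1 + snr), so node i's
    signal is sqrt(w)*s_c(i,t) + sqrt(1-w)*eps_i with both components scaled
    to unit variance.
    """

    n_subjects: int = 1
    n_nodes: int = 100
    n_volumes: int = 900
    tr_seconds: float = 0.675
    n_communities: int = 4
    #: (node index, switch time in volumes, new community label)
    switch_schedule: list[tuple[int, int, int]] = field(default_factory=list)
    #: (node i, node j, modulation amplitude in [0, 1])
    dynamic_edges: list[tuple[int, int, float]] = field(default_factory=list)
    #: period (volumes) of the sinusoidal coupling modulation on dynamic edges;
    #: keep >= 2x the analysis window length so window-level SD is elevated
    dynamic_edge_period: int = 300
    passband_hz: tuple[float, float] = (0.01, 0.08)
    snr: float = 4.0
    #: (metric name, target correlation in [-1, 1]) between behavioral scores
    #: and the planted per-subject metric
    score_coupling: tuple[str, float] = ("flexibility_global", 0.0)
    #: respiratory pseudomotion amplitude (mm) when enabled
    respiratory_amplitude_mm: float = 0.1
    respiratory_freq_hz: float = 0.3
    motion_step_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 1 or self.n_volumes < 2:
            raise ValueError("n_subjects, n_nodes must be >= 1 and n_volumes >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_nodes:
            raise ValueError("n_communities must lie in [1, n_nodes]")
        nyquist = 0.5 / self.tr_seconds
        low, high = self.passband_hz
        if not 0 < low < high < nyquist:
            raise ValueError(
                f"passband ({low}, {high}) must satisfy 0 < low < high < "
                f"Nyquist = {nyquist:.4g} Hz"
            )
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for node, t, community in self.switch_schedule:
            if not 0 <= node < self.n_nodes:
                raise ValueError(f"switch node {node} out of range [0, {self.n_nodes})")
            if not 0 < t < self.n_volumes:
                raise ValueError(
                    f"switch time {t} must lie strictly inside (0, {self.n_volumes})"
                )
            if not 0 <= community < self.n_communities:
                raise ValueError(f"switch target community {community} out of range")
        for i, j, amp in self.dynamic_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ValueError(f"dynamic edge ({i},{j}) must join two distinct nodes < n_nodes")
            if not 0 <= amp <= 1:
                raise ValueError(f"dynamic edge amplitude {amp} must lie in [0, 1]")
        if abs(self.score_coupling[1]) > 1:
            raise ValueError("score coupling |rho| must be <= 1")


@dataclass
class SyntheticGroundTruth:
    """What was planted, for downstream recovery tests."""

    #: epoch x node community labels (epochs delimited by the switch times)
    community_assignment: np.ndarray
    #: volume index at which each epoch starts
    epoch_starts: np.ndarray
    switching_nodes: set[int]
    dynamic_edges: set[tuple[int, int]]
    #: latent per-subject trait that scores are coupled to
    planted_metric: float
    subject_seed: int


def _subject_rngs(config: SyntheticConfig, subject_seed: int) -> dict[str, np.random.Generator]:
    """One independent stream per purpose, all derived from (seed, subject_seed)."""
    root = np.random.SeedSequence([config.seed, subject_seed])
    children = root.spawn(len(_RNG_PURPOSES))
    return {name: np.random.default_rng(s) for name, s in zip(_RNG_PURPOSES, children)}


def _bandlimited_noise(
    rng: np.random.Generator,
    n_samples: int,
    n_signals: int,
    tr_seconds: float,
    passband: tuple[float, float],
) -> np.ndarray:
    """Unit-variance white noise restricted to the passband.

    Filtering is done by zeroing rFFT bins outside the band, which puts all
    signal power strictly inside the passband (no filter roll-off leakage).
    """
    white = rng.standard_normal((n_samples, n_signals))
    freqs = np.fft.rfftfreq(n_samples, d=tr_seconds)
    spectrum = np.fft.rfft(white, axis=0)
    keep = (freqs >= passband[0]) & (freqs <= passband[1])
    spectrum[~keep] = 0.0
    out = np.fft.irfft(spectrum, n=n_samples, axis=0)
    sd = out.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return out / sd


def _community_labels(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-wise node->community labels implied by the switch schedule."""
    base = np.arange(config.n_nodes) % config.n_communities
    times = sorted({t for _, t, _ in config.switch_schedule})
    starts = np.array([0] + times, dtype=int)
    labels = np.empty((len(starts), config.n_nodes), dtype=int)
    current = base.copy()
    labels[0] = current
    for e, t in enumerate(times, start=1):
        for node, st, community in config.switch_schedule:
            if st == t:
                current[node] = community
        labels[e] = current
    return labels, starts


def generate_bold(
    config: SyntheticConfig, subject_seed: int
) -> tuple[ParcellatedTimeSeries, SyntheticGroundTruth]:
    """Generate one subject's parcellated BOLD-like series plus ground truth.

    Node i's signal at volume t is sqrt(w)*s_c(i,t)(t) + sqrt(1-w)*eps_i(t),
    where s_c are community-shared band-limited signals, c(i,t) follows the
    switch schedule, and w = snr/(1+snr).  Dynamic edges add an epoch-varying
    cross-loading of the partner's community signal, modulated sinusoidally
    with period ``dynamic_edge_period``.
    """
    rngs = _subject_rngs(config, subject_seed)
    T, N = config.n_volumes, config.n_nodes

    community_signals = _bandlimited_noise(
        rngs["signal"], T, config.n_communities, config.tr_seconds, config.passband_hz
    )
    noise = _bandlimited_noise(
        rngs["noise"], T, N, config.tr_seconds, config.passband_hz
    )

    labels, starts = _community_labels(config)
    # per-volume community membership
    epoch_of_volume = np.searchsorted(starts, np.arange(T), side="right") - 1
    member = labels[epoch_of_volume]  # T x N

    w = config.snr / (1.0 + config.snr)
    t_idx = np.arange(T)
    shared = community_signals[t_idx[:, None], member]  # T x N
    values = np.sqrt(w) * shared + np.sqrt(1.0 - w) * noise

    for i, j, amp in config.dynamic_edges:
        modulation = amp * np.sin(2.0 * np.pi * t_idx / config.dynamic_edge_period)
        partner = community_signals[t_idx, member[:, j]]
        values[:, i] = values[:, i] + modulation * partner

    series = ParcellatedTimeSeries(
        values=values,
        tr_seconds=config.tr_seconds,
        node_labels=[f"node_{k:03d}" for k in range(N)],
        subject_id=f"sub-{subject_seed:04d}",
        provenance=["synthetic"],
    )
    truth = SyntheticGroundTruth(
        community_assignment=labels,
        epoch_starts=starts,
        switching_nodes={node for node, _, _ in config.switch_schedule},
        dynamic_edges={(min(i, j), max(i, j)) for i, j, _ in config.dynamic_edges},
        planted_metric=float(rngs["trait"].standard_normal()),
        subject_seed=subject_seed,
    )
    return series, truth


def generate_motion(
    config: SyntheticConfig, subject_seed: int, include_respiratory: bool = True
) -> MotionTrace:
    """Generate a T x 6 realignment trace (mm translations, rad rotations).

    The base trace is a smoothed random walk (slow drift, the dominant real
    head-motion signature).  With ``include_respiratory`` a sinusoid at
    ``respiratory_freq_hz`` (~0.3 Hz) is added to the translations, emulating
    the respiratory pseudomotion visible at multiband sampling rates.
    """
    rng = _subject_rngs(config, subject_seed)["motion"]
    T = config.n_volumes
    steps = rng.standard_normal((T, 6)) * config.motion_step_mm
    walk = np.cumsum(steps, axis=0)
    if T >= 11:  # moving-average smoothing to keep drift slow
        kernel = np.ones(11) / 11.0
        walk = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)
    walk[:, 3:] *= 0.01  # rotations (rad) are ~2 orders below translations (mm)

    if include_respiratory:
        t = np.arange(T) * config.tr_seconds
        phase = rng.uniform(0, 2 * np.pi, size=3)
        resp = config.respiratory_amplitude_mm * np.sin(
            2 * np.pi * config.respiratory_freq_hz * t[:, None] + phase
        )
        walk[:, :3] = walk[:, :3] + resp

    return MotionTrace(walk[:, :3], walk[:, 3:], config.tr_seconds)


# Questionnaire shapes emulated by the score generator: item counts of the
# 10-item CD-RISC, the 6-item BRS and the 13-item RS short forms.
SCALE_ITEMS = {"cdrisc": 10, "brs": 6, "rs": 13}


def generate_scores(
    ground_truths: list[SyntheticGroundTruth],
    coupling: tuple[str, float] | None = None,
    seed: int = 0,
    inter_item_r: float = 0.5,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Generate questionnaire-like scores coupled to the planted metric.

    ``rho`` is the target *rank* (Spearman) correlation between the score
    and the planted metric, matching how the coupling is later estimated.
    For jointly Gaussian variables a Pearson correlation r_p yields Spearman
    (6/pi)*asin(r_p/2), so the generator mixes with the inverse,
    r_p = 2*sin(pi*rho/6).  Each scale's latent total
    s = r_p*z(metric) + sqrt(1-r_p^2)*e is split into items x_j = s/k + d_j
    with zero-sum deviations d, so items always sum exactly to the score.
    The deviation variance is chosen so the expected inter-item correlation
    equals ``inter_item_r`` (sigma_d^2 = Var(s)*(1-r) / (k*(1+r*(k-1)))).

    Returns a tidy table with one row per subject: ``<scale>_total`` and
    ``<scale>_item<j>`` columns for each of the three scales, plus the
    planted metric and plausible covariates (age, gender, mean_fd column left
    to the pipeline).
    """
    if len(ground_truths) < 3:
        raise ValueError("need at least 3 subjects to generate scores")
    if coupling is None:
        coupling = config.score_coupling if config is not None else ("planted", 0.0)
    metric_name, rho = coupling
    if abs(rho) > 1:
        raise ValueError(f"|rho| = {abs(rho)} exceeds 1")
    if not 0 <= inter_item_r <= 1:
        raise ValueError("inter_item_r must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_003]))
    n = len(ground_truths)
    metric = np.array([gt.planted_metric for gt in ground_truths], dtype=float)
    z = (metric - metric.mean()) / metric.std(ddof=0) if metric.std(ddof=0) > 0 else metric

    out: dict[str, np.ndarray] = {
        "subject_seed": np.array([gt.subject_seed for gt in ground_truths]),
        "planted_metric": metric,
    }
    r_p = 2.0 * np.sin(np.pi * rho / 6.0)  # Gaussian-copula inverse of Spearman
    for scale, k in SCALE_ITEMS.items():
        noise = rng.standard_normal(n)
        total = r_p * z + np.sqrt(max(0.0, 1.0 - r_p**2)) * noise
        var_s = max(total.var(ddof=0), np.finfo(float).tiny)
        sigma_d = np.sqrt(var_s * (1.0 - inter_item_r) / (k * (1.0 + inter_item_r * (k - 1))))
        e = rng.standard_normal((n, k)) * sigma_d
        deviations = e - e.mean(axis=1, keepdims=True)
        items = total[:, None] / k + deviations
        out[f"{scale}_total"] = items.sum(axis=1)
        for j in range(k):
            out[f"{scale}_item{j + 1}"] = items[:, j]

    out["age"] = rng.integers(18, 35, size=n).astype(float)
    out["gender"] = rng.choice(
        ["female", "male", "diverse"], size=n, p=[0.49, 0.49, 0.02]
    )
    return pd.DataFrame(out)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ParcellatedTimeSeries], list[MotionTrace], list[SyntheticGroundTruth], pd.DataFrame]:
    """Generate a full cohort: series, motion, ground truth and scores."""
    all_series, motions, truths = [], [], []
    for s in range(config.n_subjects):
        series, truth = generate_bold(config, subject_seed=s)
        all_series.append(series)
        truths.append(truth)
        motions.append(generate_motion(config, subject_seed=s))
    scores = generate_scores(truths, coupling=config.score_coupling, seed=config.seed) \
        if config.n_subjects >= 3 else pd.DataFrame()
    return all_series, motions, truths, scores


def signal_band_fraction(series: ParcellatedTimeSeries, passband: tuple[float, float]) -> float:
    """Fraction of total signal power inside the passband (mean over nodes).

    Computed by periodogram integration; used to assert spectral compliance
    of generated data.
    """
    freqs, pxx = sps.periodogram(series.values, fs=1.0 / series.tr_seconds, axis=0)
    inband = (freqs >= passband[0]) & (freqs <= passband[1])
    total = pxx.sum(axis=0)
    total[total == 0] = np.finfo(float).tiny
    return float(np.mean(pxx[inband].sum(axis=0) / total))
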