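"""Time-varying functional connectivity (TVFC).

Sliding-window Pearson correlation with Hamming tapering, edge-wise SD as a
proxy for connectivity dynamics, phase-randomized surrogate testing of those
SDs, and the resulting "dynamic degree" per node.

The surrogate construction rotates the Fourier phases of *all* node signals
by the same random phase vector, which preserves each signal's amplitude
spectrum (hence autocorrelation and power spectral density) and every pair's
cross-spectrum (hence the stationary cross-correlation structure), while
destroying any genuine time-localized coupling changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import squareform

from .preprocess import ParcellatedTimeSeries
from .stats import fdr_bh

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Sliding-window geometry and taper.

    ``overlapping`` windows advance by ``step_samples`` (default 1 TR);
    ``nonoverlapping`` windows tile the series with step == length.
    """

    length_samples: int
    step_samples: int = 1
    taper: str = "hamming"
    scheme: str = "overlapping"

    def __post_init__(self) -> None:
        if self.scheme not in ("overlapping", "nonoverlapping"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.taper not in ("hamming", "none"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.length_samples < 2:
            raise ValueError("window length must be >= 2 samples")
        if self.scheme == "nonoverlapping":
            self.step_samples = self.length_samples
        elif self.step_samples < 1:
            raise ValueError("step must be >= 1")


@dataclass
class ConnectivityStack:
    """Ordered sequence of symmetric N x N windowed connectivity matrices."""

    layers: np.ndarray  # L x N x N
    window_starts: np.ndarray
    transform_state: str = "raw_r"  # or "nonneg_z"
    tr_seconds: float | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass
class EdgeDynamicsResult:
    """Per-edge SD, surrogate p-values and FDR-significance mask.

    Edges are the N(N-1)/2 unordered node pairs in ``squareform`` order.
    """

    edge_sd: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_surrogates: int
    fdr_alpha: float


@dataclass
class NodeMetricVector:
    """Per-node values of one reconfiguration metric."""

    metric_name: str  # flexibility | promiscuity | degree
    values: np.ndarray
    level: str = "node"


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def count_windows(T: int, spec: WindowSpec) -> int:
    """Number of windows a series of T samples yields under ``spec``."""
    if spec.length_samples > T:
        raise ValueError(f"window length {spec.length_samples} exceeds T={T}")
    if spec.scheme == "nonoverlapping":
        return T // spec.length_samples
    return (T - spec.length_samples) // spec.step_samples + 1


def hamming_weights(length: int) -> np.ndarray:
    """Hamming taper w(n) = 0.54 - 0.46*cos(2*pi*n/(length-1))."""
    if length < 2:
        raise ValueError("taper length must be >= 2")
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))


def _window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    L = count_windows(T, spec)
    return np.arange(L) * spec.step_samples


def windowed_correlation(series: ParcellatedTimeSeries, spec: WindowSpec) -> ConnectivityStack:
    """Tapered Pearson correlation between all node pairs, per window.

    The taper enters as observation weights in a weighted Pearson
    correlation (weighted means and covariances); a flat taper reduces it to
    the ordinary Pearson coefficient.  Edges involving a zero-variance node
    within a window are set to 0 and logged.
    """
    X = series.values
    T, N = X.shape
    starts = _window_starts(T, spec)
    W = spec.length_samples

    if spec.taper == "hamming":
        w = hamming_weights(W)
    else:
        w = np.ones(W)
    w = w / w.sum()

    # windows tensor: L x W x N (a view; no copy)
    win = sliding_window_view(X, W, axis=0)[starts]  # L x N x W
    win = win.transpose(0, 2, 1)  # L x W x N

    mean = np.einsum("w,lwn->ln", w, win)
    centered = win - mean[:, None, :]
    weighted = centered * w[None, :, None]
    cov = np.matmul(weighted.transpose(0, 2, 1), centered)  # L x N x N
    var = np.einsum("lnn->ln", cov).copy()

    zero_var = var <= 0
    if zero_var.any():
        logger.warning(
            "zero-variance node(s) within %d window(s); their edges set to 0",
            int(zero_var.any(axis=1).sum()),
        )
        var[zero_var] = 1.0
    denom = np.sqrt(var[:, :, None] * var[:, None, :])
    corr = cov / denom
    corr = np.clip(corr, -1.0, 1.0)
    # zero out edges of degenerate nodes, restore unit diagonal
    if zero_var.any():
        mask = zero_var[:, :, None] | zero_var[:, None, :]
        corr[mask] = 0.0
    idx = np.arange(N)
    corr[:, idx, idx] = 1.0
    corr = 0.5 * (corr + corr.transpose(0, 2, 1))

    return ConnectivityStack(
        layers=corr,
        window_starts=starts,
        transform_state="raw_r",
        tr_seconds=series.tr_seconds,
        provenance=series.provenance
        + [f"windowed_correlation[len={W},step={spec.step_samples},"
           f"taper={spec.taper},scheme={spec.scheme}]"],
    )


# ---------------------------------------------------------------------------
# Edge dynamics
# ---------------------------------------------------------------------------

def edge_sd(stack: ConnectivityStack) -> np.ndarray:
    """Sample SD of each edge's correlation across layers (squareform order)."""
    if stack.transform_state != "raw_r":
        raise ValueError("edge SD is defined on raw correlations")
    if stack.n_layers < 2:
        raise ValueError("need at least 2 layers to compute an SD")
    iu = np.triu_indices(stack.n_nodes, k=1)
    edges = stack.layers[:, iu[0], iu[1]]  # L x E
    return edges.std(axis=0, ddof=1)


def phase_randomize(series: ParcellatedTimeSeries, seed: int | np.random.Generator) -> ParcellatedTimeSeries:
    """Phase-randomized surrogate with shared phases across nodes.

    All node signals' discrete-Fourier phases are rotated by the same
    uniformly random phase vector (conjugate-symmetric; DC and, for even T,
    the Nyquist bin are left untouched), then inverse-transformed back to a
    real series.  Amplitude spectra and all cross-spectra — hence the full
    stationary auto- and cross-correlation structure — are preserved.
    """
    T = series.n_volumes
    if T < 4:
        raise ValueError("need at least 4 samples to phase-randomize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    spectrum = np.fft.rfft(series.values, axis=0)
    n_bins = spectrum.shape[0]
    rotatable = np.arange(1, n_bins - 1 if T % 2 == 0 else n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=rotatable.size)
    spectrum[rotatable] *= np.exp(1j * phases)[:, None]
    values = np.fft.irfft(spectrum, n=T, axis=0)

    out = ParcellatedTimeSeries(
        values=values,
        tr_seconds=series.tr_seconds,
        node_labels=list(series.node_labels),
        subject_id=series.subject_id,
        provenance=series.provenance + ["phase_randomize"],
    )
    return out


def surrogate_test(
    series: ParcellatedTimeSeries,
    spec: WindowSpec,
    n_surrogates: int = 500,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> EdgeDynamicsResult:
    """Test each edge's windowed-correlation SD against a phase-random null.

    p = #{SD_surr >= SD_real} / n_surrogates per edge (no +1 correction, so
    p = 0 is attainable), followed by Benjamini-Hochberg FDR over all
    N(N-1)/2 edges of the subject.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    observed = edge_sd(windowed_correlation(series, spec))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    exceed = np.zeros_like(observed, dtype=int)
    for _ in range(n_surrogates):
        surr = phase_randomize(series, rng)
        sd = edge_sd(windowed_correlation(surr, spec))
        exceed += sd >= observed
    p = exceed / n_surrogates
    significant, _ = fdr_bh(p, alpha=fdr_alpha)
    return EdgeDynamicsResult(
        edge_sd=observed,
        p_values=p,
        significant=significant,
        n_surrogates=n_surrogates,
        fdr_alpha=fdr_alpha,
    )


def node_degree(
    result: EdgeDynamicsResult, n_nodes: int, all_edges_denominator: bool = False
) -> tuple[NodeMetricVector, np.ndarray]:
    """Dynamic degree: per node, the count of significant ("dynamic") edges.

    Returns the integer degree vector and a companion percentage, by default
    relative to the N-1 edges incident on each node (set
    ``all_edges_denominator`` to divide by all N(N-1)/2 edges instead).
    """
    expected = n_nodes * (n_nodes - 1) // 2
    if result.significant.shape[0] != expected:
        raise ValueError(
            f"mask has {result.significant.shape[0]} edges, expected {expected} for N={n_nodes}"
        )
    adj = squareform(result.significant.astype(float))
    degree = adj.sum(axis=1)
    denom = expected if all_edges_denominator else (n_nodes - 1)
    pct = degree / denom * 100.0
    return NodeMetricVector("degree", degree, level="node"), pct
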