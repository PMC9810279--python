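"""Parcel-level preprocessing: denoising, motion quantification, QC, down-sampling.

This module operates on parcellated BOLD time series (one averaged signal per
atlas region) and the realignment parameters that accompany them.  It provides

* framewise displacement (FD) in the Power convention, plus its low-pass
  filtered variant FD_filt used to suppress respiratory pseudomotion in
  fast-TR multiband acquisitions,
* motion-based subject exclusion rules,
* the 36-parameter and lenient 26-parameter nuisance-regression models,
* band-pass filtering + confound regression of parcel time series, and
* decimation to a slower virtual TR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Head radius (mm) used to convert rotational displacement to millimetres.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Default low-pass cutoff (Hz) for filtered framewise displacement.
DEFAULT_FD_FILTER_CUTOFF_HZ = 0.2

#: Motion-QC exclusion thresholds: mean FD_filt (mm) and the number of
#: volumes allowed above the per-volume spike threshold (mm).
QC_MEAN_FD_MM = 0.2
QC_SPIKE_FD_MM = 0.25
QC_MAX_SPIKES = 20


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ParcellatedTimeSeries:
    """A T x N matrix of region-averaged BOLD signals.

    Parameters
    ----------
    values
        Array of shape (T, N); rows are volumes, columns are atlas nodes.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    node_labels
        Unique names of the N nodes.
    subject_id
        Identifier carried through the pipeline for error reporting.
    provenance
        Ordered record of the transforms applied so far.
    """

    values: np.ndarray
    tr_seconds: float
    node_labels: list[str]
    subject_id: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("values must be a T x N matrix with T >= 2")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.node_labels) != self.values.shape[1]:
            raise ValueError("node_labels length must match number of columns")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node_labels must be unique")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters over time.

    ``translations`` are in millimetres, ``rotations`` in radians; both have
    shape (T, 3) and share the sampling interval of the BOLD series they
    accompany.
    """

    translations: np.ndarray
    rotations: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.shape != self.rotations.shape:
            raise ValueError("translations and rotations must have equal shape")
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("motion trace must be T x 3 per component")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Return the T x 6 matrix [trans_x..z, rot_x..z]."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class ConfoundMatrix:
    """Nuisance regressors assembled for confound regression."""

    columns: np.ndarray
    column_names: list[str]
    model_name: str

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.shape[1] != len(self.column_names):
            raise ValueError("column count does not match names")
        expected = {"36-parameter": 36, "26-parameter": 26}.get(self.model_name)
        if expected is not None and self.columns.shape[1] != expected:
            raise ValueError(
                f"{self.model_name} model must have {expected} columns, "
                f"got {self.columns.shape[1]}"
            )


@dataclass
class QCDecision:
    """Outcome of the motion-based exclusion rules for one subject."""

    mean_fd_filt: float
    n_volumes_over_025: int
    excluded: bool
    reason: str


# ---------------------------------------------------------------------------
# Framewise displacement and motion QC
# ---------------------------------------------------------------------------

def compute_fd(trace: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement per volume, in mm (Power convention).

    FD_t = sum of absolute backward differences of the three translations
    plus ``head_radius_mm`` times the sum of absolute backward differences of
    the three rotations.  The first volume has FD 0 by definition.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least two volumes to compute FD")
    mat = trace.as_matrix()
    if not np.isfinite(mat).all():
        raise ValueError("motion trace contains non-finite values")
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius_mm * dr])
    return fd


def filter_motion_trace(
    trace: MotionTrace,
    cutoff_hz: float = DEFAULT_FD_FILTER_CUTOFF_HZ,
    order: int = 2,
) -> MotionTrace:
    """Low-pass filter the realignment parameters (zero-phase Butterworth).

    Used to remove the ~0.3 Hz respiratory component that contaminates raw
    motion estimates at short TRs; FD computed on the result is FD_filt.
    """
    nyquist = 0.5 / trace.tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4g} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / trace.tr_seconds, output="sos")
    trans = signal.sosfiltfilt(sos, trace.translations, axis=0)
    rots = signal.sosfiltfilt(sos, trace.rotations, axis=0)
    return MotionTrace(trans, rots, trace.tr_seconds)


def qc_exclude(fd_filt: np.ndarray) -> QCDecision:
    """Apply the motion exclusion rules to a per-volume FD_filt series.

    A subject is excluded when mean FD_filt exceeds 0.2 mm, or when more than
    20 volumes have FD_filt above 0.25 mm.
    """
    fd_filt = np.asarray(fd_filt, dtype=float)
    if fd_filt.size == 0:
        raise ValueError("FD series is empty")
    mean_fd = float(fd_filt.mean())
    n_spikes = int((fd_filt > QC_SPIKE_FD_MM).sum())
    reasons = []
    if mean_fd > QC_MEAN_FD_MM:
        reasons.append("mean-FD")
    if n_spikes > QC_MAX_SPIKES:
        reasons.append("spike-count")
    return QCDecision(
        mean_fd_filt=mean_fd,
        n_volumes_over_025=n_spikes,
        excluded=bool(reasons),
        reason="+".join(reasons) if reasons else "retained",
    )


# ---------------------------------------------------------------------------
# Confound models
# ---------------------------------------------------------------------------

def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward difference along axis 0 with the first element set to 0."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_confound_model(
    trace: MotionTrace,
    wm: np.ndarray,
    csf: np.ndarray,
    gs: np.ndarray,
    model: str = "36-parameter",
) -> ConfoundMatrix:
    """Assemble a nuisance-regressor matrix.

    ``"36-parameter"``: 6 motion + WM + CSF + global signal, their backward-
    difference temporal derivatives, and the squares of all 18 (9+9+18=36).

    ``"26-parameter"``: the Friston 24-parameter motion expansion (6 motion,
    their derivatives, and the squares of those 12) plus WM and CSF means.
    """
    wm = np.asarray(wm, dtype=float).reshape(-1)
    csf = np.asarray(csf, dtype=float).reshape(-1)
    gs = np.asarray(gs, dtype=float).reshape(-1)
    T = trace.n_volumes
    for name, series in (("wm", wm), ("csf", csf), ("gs", gs)):
        if series.shape[0] != T:
            raise ValueError(f"{name} series length {series.shape[0]} != T={T}")

    motion = trace.as_matrix()
    motion_names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

    if model == "36-parameter":
        base = np.column_stack([motion, wm, csf, gs])
        base_names = motion_names + ["white_matter", "csf", "global_signal"]
        deriv = _backward_diff(base)
        expanded = np.hstack([base, deriv])
        names = base_names + [f"{n}_derivative1" for n in base_names]
        squares = expanded**2
        sq_names = [f"{n}_power2" for n in names]
        cols, col_names = np.hstack([expanded, squares]), names + sq_names
    elif model == "26-parameter":
        deriv = _backward_diff(motion)
        twelve = np.hstack([motion, deriv])
        names12 = motion_names + [f"{n}_derivative1" for n in motion_names]
        friston24 = np.hstack([twelve, twelve**2])
        names24 = names12 + [f"{n}_power2" for n in names12]
        cols = np.column_stack([friston24, wm, csf])
        col_names = names24 + ["white_matter", "csf"]
    else:
        raise ValueError(f"unknown confound model {model!r}")

    return ConfoundMatrix(cols, col_names, model)


# ---------------------------------------------------------------------------
# Temporal filtering and confound regression
# ---------------------------------------------------------------------------

def bandpass(
    x: np.ndarray,
    tr_seconds: float,
    passband: tuple[float, float],
    order: int = 1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    low, high = passband
    nyquist = 0.5 / tr_seconds
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"passband ({low}, {high}) must satisfy 0 < low < high < Nyquist={nyquist:.4g}"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def _drop_collinear(columns: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal linearly independent subset of columns (pivoted QR)."""
    from scipy.linalg import qr

    nonzero = [j for j in range(columns.shape[1]) if np.abs(columns[:, j]).max() > 0]
    if not nonzero:
        return columns[:, :0], []
    sub = columns[:, nonzero]
    r_diag_tol = max(sub.shape) * np.finfo(float).eps
    _, r, piv = qr(sub, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > r_diag_tol * diag[0]).sum()) if diag.size else 0
    keep = sorted(piv[:rank])
    kept_idx = [nonzero[j] for j in keep]
    if len(kept_idx) < columns.shape[1]:
        dropped = [names[j] for j in range(columns.shape[1]) if j not in kept_idx]
        logger.warning("dropping collinear/empty confound columns: %s", dropped)
    return columns[:, kept_idx], [names[j] for j in kept_idx]


def regress_confounds(
    series: ParcellatedTimeSeries,
    confounds: ConfoundMatrix,
    passband: tuple[float, float] = (0.01, 0.08),
) -> ParcellatedTimeSeries:
    """Demean, detrend, band-pass, and residualize against confounds.

    Each node signal is demeaned, linearly detrended, and band-pass filtered
    (first-order Butterworth, zero-phase).  Confound columns receive the same
    demean/detrend/band-pass treatment before ordinary-least-squares
    residualization, so no out-of-band nuisance variance is reintroduced.
    """
    if confounds.columns.shape[0] != series.n_volumes:
        raise ValueError("confound rows must match number of volumes")

    data = signal.detrend(series.values, axis=0, type="linear")
    data = bandpass(data, series.tr_seconds, passband)
    data = data - data.mean(axis=0)  # remove filter-transient DC residue

    conf = signal.detrend(confounds.columns, axis=0, type="linear")
    conf = bandpass(conf, series.tr_seconds, passband)
    conf = conf - conf.mean(axis=0)
    conf, kept_names = _drop_collinear(conf, confounds.column_names)

    if conf.shape[1]:
        # project out the confound span via an orthonormal basis; keeps the
        # residuals numerically orthogonal even for ill-conditioned models
        from scipy.linalg import qr

        q, _ = qr(conf, mode="economic")
        data = data - q @ (q.T @ data)

    return replace(
        series,
        values=data,
        provenance=series.provenance
        + [f"regress_confounds[{confounds.model_name},band={passband},k={len(kept_names)}]"],
    )


def downsample(
    series: ParcellatedTimeSeries,
    factor: int,
    motion: MotionTrace | None = None,
) -> ParcellatedTimeSeries | tuple[ParcellatedTimeSeries, MotionTrace]:
    """Decimate to every ``factor``-th volume (starting at index 0).

    Emulates a slower acquisition: the virtual TR is ``factor`` times the
    original.  No anti-alias filter is applied — the point is sparser
    sampling of the same underlying signal.  When a motion trace is supplied
    it is decimated on the identical grid and returned alongside.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("downsampling factor must be an integer >= 1")
    factor = int(factor)
    out = replace(
        series,
        values=series.values[::factor],
        tr_seconds=series.tr_seconds * factor,
        provenance=series.provenance + [f"downsample[x{factor}]"],
    )
    if motion is None:
        return out
    motion_out = MotionTrace(
        motion.translations[::factor],
        motion.rotations[::factor],
        motion.tr_seconds * factor,
    )
    return out, motion_out
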