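"""Brain-behavior statistics and questionnaire psychometrics.

Aggregation of node metrics to resting-state-network (RSN) and global
levels, partial Spearman correlation with nuisance covariates, BH-FDR
correction, Cronbach's alpha with the Feldt confidence interval, spatial
similarity of nodal metric maps, paired t tests, and Fisher-z power for
correlational designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PartialCorrResult:
    rho: float
    p: float
    n: int
    n_covariates: int
    degenerate: bool = False


def _metric_values(x) -> np.ndarray:
    """Accept plain arrays or NodeMetricVector-like objects."""
    return np.asarray(getattr(x, "values", x), dtype=float)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(node_metrics, mapping: dict[str, str] | pd.Series,
              node_labels: list[str] | None = None) -> pd.Series:
    """Average node values within each RSN plus a global mean.

    ``mapping`` maps node label -> RSN name; every node must be mapped.
    Returns a Series indexed by RSN name plus ``"global"``.
    """
    values = _metric_values(node_metrics)
    if node_labels is None:
        node_labels = [f"node_{k:03d}" for k in range(values.size)]
    if isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    missing = [lab for lab in node_labels if lab not in mapping]
    if missing:
        raise KeyError(f"nodes without an RSN assignment: {missing}")
    df = pd.DataFrame({"value": values, "rsn": [mapping[lab] for lab in node_labels]})
    out = df.groupby("rsn", sort=True)["value"].mean()
    out.loc["global"] = values.mean()
    return out


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------

def encode_covariates(covariates: pd.DataFrame | None) -> np.ndarray:
    """Numeric design matrix from a covariate table.

    Numeric columns pass through; categorical columns (e.g. gender,
    including a "diverse" level) become indicator columns with the most
    frequent level as reference.
    """
    if covariates is None or len(covariates.columns) == 0:
        n = 0 if covariates is None else len(covariates)
        return np.empty((n, 0))
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = col.value_counts().index.tolist()
            for level in levels[1:]:  # reference = most frequent level
                cols.append((col == level).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(covariates), 0))


def partial_spearman(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    x, y and numerically encoded covariates are rank-transformed; the ranks
    of x and y are residualized against the covariate ranks (plus an
    intercept) by ordinary least squares, and the Pearson correlation of the
    residuals is returned with a two-sided p from the t distribution on
    n - 2 - k degrees of freedom.  With no covariates this reduces exactly
    to the plain Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        Z = encode_covariates(covariates)
    elif covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
    k = Z.shape[1]
    n = x.size
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 observations (n={n}, k={k})")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PartialCorrResult(np.nan, np.nan, n, k, degenerate=True)

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(k)])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    sx, sy = ex.std(), ey.std()
    # residual variance indistinguishable from rounding noise: a covariate
    # explains x or y perfectly and the partial correlation is undefined
    tol = 1e-8 * max(rx.std(), ry.std())
    if sx <= tol or sy <= tol:
        return PartialCorrResult(np.nan, np.nan, n, k, degenerate=True)
    rho = float(np.dot(ex, ey) / (n * sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(rho, p, n, k)


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (rejection mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Psychometrics
# ---------------------------------------------------------------------------

def cronbach_alpha(items: np.ndarray | pd.DataFrame, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha for a subjects x items matrix, with Feldt 95% CI.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total);
    the confidence interval follows Feldt's F-distribution result with
    df1 = n - 1 and df2 = (n - 1)(k - 1).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need a subjects x items matrix with k >= 2, n >= 3")
    n, k = X.shape
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)

    c = 1.0 - ci
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lower = 1.0 - (1.0 - alpha) * sps.f.ppf(1.0 - c / 2, df1, df2)
    upper = 1.0 - (1.0 - alpha) * sps.f.ppf(c / 2, df1, df2)
    return float(alpha), (float(lower), float(upper))


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def spatial_similarity(a, b) -> tuple[float, float]:
    """Spearman correlation across nodes of two metric maps (rho, p)."""
    va, vb = _metric_values(a), _metric_values(b)
    if va.size != vb.size or va.size < 3:
        raise ValueError("metric vectors must have equal length >= 3")
    rho, p = sps.spearmanr(va, vb)
    return float(rho), float(p)


def paired_t(a, b) -> tuple[float, int, float]:
    """Paired t test: (t, df, two-sided p); zero difference variance flagged."""
    va, vb = _metric_values(a), _metric_values(b)
    if va.size != vb.size or va.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = va - vb
    if d.std(ddof=1) == 0:
        raise ValueError("zero difference variance; paired t undefined")
    t, p = sps.ttest_rel(va, vb)
    return float(t), va.size - 1, float(p)


def correlation_power(n: int, rho: float, alpha: float = 0.05) -> float:
    """Two-sided power to detect a correlation of size rho at sample size n.

    Fisher-z approximation: with z = atanh(rho) and critical value
    z_(1-alpha/2), power = Phi(z*sqrt(n-3) - z_crit) + Phi(-z*sqrt(n-3) - z_crit).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    z_eff = np.arctanh(rho)
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    shift = z_eff * np.sqrt(n - 3)
    return float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))


# ---------------------------------------------------------------------------
# The full correlation grid
# ---------------------------------------------------------------------------

def correlation_grid(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fdr_family: tuple[str, ...] = ("metric", "level", "scale"),
) -> pd.DataFrame:
    """All (scale x metric x level x feature) partial Spearman correlations.

    ``metrics`` columns must be named ``<metric>__<level>__<feature>``
    (e.g. ``flexibility__global__global``, ``degree__rsn__visual``);
    ``scores`` holds one column per questionnaire total.  All three tables
    must be indexed by the same subjects.  FDR correction is applied within
    each family defined by ``fdr_family`` (default: metric x level x scale).
    """
    if not metrics.index.equals(scores.index) or (
        covariates is not None and not metrics.index.equals(covariates.index)
    ):
        raise ValueError(
            "subject indices are misaligned: "
            f"metrics={list(metrics.index)}, scores={list(scores.index)}"
            + (f", covariates={list(covariates.index)}" if covariates is not None else "")
        )
    rows = []
    for col in metrics.columns:
        try:
            metric, level, feature = col.split("__", 2)
        except ValueError as err:
            raise ValueError(
                f"metric column {col!r} is not of the form metric__level__feature"
            ) from err
        for scale in scores.columns:
            res = partial_spearman(metrics[col], scores[scale], covariates)
            rows.append(
                {
                    "scale": scale,
                    "metric": metric,
                    "level": level,
                    "feature": feature,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "degenerate": res.degenerate,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    table["significant"] = False
    for _, idx in table.groupby(list(fdr_family)).groups.items():
        sub = table.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            reject, p_adj = fdr_bh(sub.loc[ok, "p"].to_numpy(), alpha=alpha)
            table.loc[sub.index[ok], "p_fdr"] = p_adj
            table.loc[sub.index[ok], "significant"] = reject
    return table
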