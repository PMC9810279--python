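"""Aggregation, partial Spearman, FDR, psychometrics, power, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netreconfig import (
    aggregate,
    correlation_grid,
    correlation_power,
    cronbach_alpha,
    fdr_bh,
    paired_t,
    partial_spearman,
    spatial_similarity,
)


class TestAggregate:
    def test_uniform_values_propagate(self):
        mapping = {f"node_{k:03d}": f"rsn_{k % 2}" for k in range(6)}
        out = aggregate(np.full(6, 0.7), mapping)
        assert np.allclose(out.values, 0.7)

    def test_two_rsn_arithmetic(self):
        mapping = {"node_000": "a", "node_001": "a", "node_002": "b"}
        out = aggregate(np.array([0.2, 0.4, 0.6]), mapping)
        assert out["a"] == pytest.approx(0.3)
        assert out["b"] == pytest.approx(0.6)
        assert out["global"] == pytest.approx(0.4)

    def test_singleton_rsn_equals_node(self):
        mapping = {"node_000": "solo", "node_001": "rest", "node_002": "rest"}
        out = aggregate(np.array([0.9, 0.1, 0.2]), mapping)
        assert out["solo"] == pytest.approx(0.9)

    def test_unmapped_node_is_hard_error(self):
        with pytest.raises(KeyError, match="node_002"):
            aggregate(np.zeros(3), {"node_000": "a", "node_001": "a"})


class TestPartialSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(0, 5, 20)
        y = np.exp(x)
        res = partial_spearman(x, y)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_no_covariates_equals_plain_spearman(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = partial_spearman(x, y)
        rho, _ = spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-12)

    def test_covariate_identical_to_x_flagged_degenerate(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = partial_spearman(x, y, covariates=x[:, None])
        assert res.degenerate

    def test_constant_input_flagged(self):
        res = partial_spearman(np.ones(10), np.arange(10.0))
        assert res.degenerate and np.isnan(res.rho)

    def test_matches_bruteforce_residual_oracle(self, rng):
        """12-subject fixture against an explicit rank-residual computation."""
        from scipy.stats import rankdata, t as t_dist

        n = 12
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=(n, 2))
        res = partial_spearman(x, y, covariates=z)

        rx, ry = rankdata(x), rankdata(y)
        Z = np.column_stack([np.ones(n), rankdata(z[:, 0]), rankdata(z[:, 1])])
        hx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        hy = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        rho = np.corrcoef(hx, hy)[0, 1]
        df = n - 2 - 2
        t = rho * np.sqrt(df / (1 - rho**2))
        p = 2 * t_dist.sf(abs(t), df)
        assert res.rho == pytest.approx(rho, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")

        n = 40
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        df["y"] += 0.4 * df["x"]
        res = partial_spearman(df["x"], df["y"], covariates=df[["c1", "c2"]])
        pg = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert res.rho == pytest.approx(float(pg["r"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(pg["p_val"].iloc[0]), rel=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman(np.arange(4.0), np.arange(4.0), covariates=np.ones((4, 2)))


class TestFdrBH:
    def test_stepup_thresholds_all_rejected(self):
        reject, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert reject.all()

    def test_flat_half_none_rejected(self):
        reject, p_adj = fdr_bh(np.full(8, 0.5), alpha=0.05)
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 0.5)

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh(np.array([0.04]), alpha=0.05)
        assert reject[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_literal_stepup_definition(self, p_list):
        """Literal BH: largest k with p_(k) <= k*alpha/m; reject those ranks."""
        alpha = 0.05
        p = np.array(p_list)
        reject, p_adj = fdr_bh(p, alpha=alpha)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        sorted_p = p[order]
        thresholds = (np.arange(1, m + 1) / m) * alpha
        below = np.nonzero(sorted_p <= thresholds)[0]
        expected = np.zeros(m, dtype=bool)
        if below.size:
            expected[order[: below[-1] + 1]] = True
        np.testing.assert_array_equal(reject, expected)
        # adjusted p monotone nondecreasing in raw-p order
        assert np.all(np.diff(p_adj[order]) >= -1e-12)


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self, rng):
        x = rng.normal(size=30)
        items = np.column_stack([x, x, x, x])
        alpha, _ = cronbach_alpha(items)
        assert alpha == pytest.approx(1.0)

    def test_two_item_closed_form(self):
        # unit variances and covariance 0.5 -> alpha = 2*(1 - 2/3) = 2/3
        rng = np.random.default_rng(0)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        items = rng.multivariate_normal([0, 0], cov, size=200_000)
        alpha, _ = cronbach_alpha(items)
        assert alpha == pytest.approx(2 / 3, abs=0.01)

    def test_independent_items_alpha_near_zero(self, rng):
        items = rng.normal(size=(5000, 6))
        alpha, _ = cronbach_alpha(items)
        assert abs(alpha) < 0.1

    def test_ci_brackets_alpha_and_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")

        common = rng.normal(size=80)
        items = common[:, None] + rng.normal(size=(80, 5))
        alpha, (lo, hi) = cronbach_alpha(items)
        assert lo < alpha < hi
        pg_alpha, pg_ci = pingouin.cronbach_alpha(pd.DataFrame(items))
        assert alpha == pytest.approx(pg_alpha, abs=1e-10)
        assert lo == pytest.approx(pg_ci[0], abs=0.01)
        assert hi == pytest.approx(pg_ci[1], abs=0.01)

    def test_zero_total_variance_flagged(self):
        items = np.tile([1.0, -1.0], (10, 1))
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(items)


class TestSpatialSimilarity:
    def test_self_similarity_one(self, rng):
        a = rng.normal(size=10)
        rho, _ = spatial_similarity(a, a)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        a = np.arange(10.0)
        rho, _ = spatial_similarity(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        from scipy.stats import rankdata

        a = rng.normal(size=15)
        b = rng.normal(size=15)
        rho, _ = spatial_similarity(a, b)
        ra, rb = rankdata(a), rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)


class TestPairedT:
    def test_df_formula(self, rng):
        t, df, p = paired_t(rng.normal(size=100), rng.normal(size=100))
        assert df == 99

    def test_zero_difference_variance_flagged(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError, match="difference variance"):
            paired_t(a, a + 1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        t, df, p = paired_t(a, b)
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        from scipy.stats import t as t_dist

        assert t == pytest.approx(expected_t, abs=1e-12)
        assert p == pytest.approx(2 * t_dist.sf(abs(expected_t), 24), abs=1e-12)


class TestCorrelationPower:
    def test_study_sample_size_exceeds_99(self):
        assert correlation_power(52, 0.55) > 0.99

    def test_null_effect_power_equals_alpha(self):
        assert correlation_power(100, 0.0, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_n(self):
        powers = [correlation_power(n, 0.3) for n in (10, 20, 50, 100, 200)]
        assert np.all(np.diff(powers) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            correlation_power(3, 0.5)
        with pytest.raises(ValueError):
            correlation_power(50, 1.0)


class TestCorrelationGrid:
    def _tables(self, n=30, rho=0.0, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"sub-{i:03d}" for i in range(n)]
        metric = rng.normal(size=n)
        metrics = pd.DataFrame(
            {
                "flexibility__global__global": metric,
                "promiscuity__global__global": rng.normal(size=n),
                "degree__global__global": rng.normal(size=n),
            },
            index=idx,
        )
        r_p = 2 * np.sin(np.pi * rho / 6)  # target rank correlation rho
        scores = pd.DataFrame(
            {
                "cdrisc_total": r_p * metric + np.sqrt(1 - r_p**2) * rng.normal(size=n),
                "brs_total": rng.normal(size=n),
                "rs_total": rng.normal(size=n),
            },
            index=idx,
        )
        covs = pd.DataFrame(
            {
                "age": rng.integers(18, 35, size=n).astype(float),
                "gender": rng.choice(["f", "m"], size=n),
                "mean_fd": rng.uniform(0.02, 0.15, size=n),
            },
            index=idx,
        )
        return metrics, scores, covs

    def test_grid_size_three_by_three(self):
        metrics, scores, covs = self._tables()
        grid = correlation_grid(metrics, scores, covs)
        assert len(grid) == 9
        assert set(grid["metric"]) == {"flexibility", "promiscuity", "degree"}

    def test_planted_coupling_recovered(self):
        metrics, scores, covs = self._tables(n=200, rho=0.6, seed=0)
        grid = correlation_grid(metrics, scores, covs)
        row = grid[(grid["metric"] == "flexibility") & (grid["scale"] == "cdrisc_total")]
        assert abs(float(row["rho"].iloc[0]) - 0.6) < 0.1
        assert bool(row["significant"].iloc[0])

    def test_misaligned_subjects_hard_error(self):
        metrics, scores, covs = self._tables()
        scores = scores.iloc[:-1]
        with pytest.raises(ValueError, match="misaligned"):
            correlation_grid(metrics, scores, covs)

    def test_determinism(self):
        m1, s1, c1 = self._tables(seed=3)
        m2, s2, c2 = self._tables(seed=3)
        g1 = correlation_grid(m1, s1, c1)
        g2 = correlation_grid(m2, s2, c2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_null_family_rejection_rate_near_alpha(self):
        """Under a global null, the family-wise rejection fraction stays small."""
        n_sig = 0
        n_rows = 0
        for seed in range(60):
            metrics, scores, covs = self._tables(n=40, rho=0.0, seed=seed + 100)
            grid = correlation_grid(metrics, scores, covs)
            n_sig += int(grid["significant"].sum())
            n_rows += len(grid)
        assert n_sig / n_rows < 0.10
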