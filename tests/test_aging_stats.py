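"""Age-association statistics: OLS, FDR, t-tests, LRT, vertexwise maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hippomicro.stats import (
    bh_fdr,
    lrt_nested,
    ols_age_model,
    pooled_t_from_summary,
    roi_summary,
    spatial_correlation_matrix,
    vertexwise_regression,
    welch_t_from_summary,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: adj_i = min over the larger-p tail of
    (n/rank)·p, capped at 1."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestOlsAgeModel:
    def test_exact_linear_relation(self, rng):
        ages = rng.uniform(19, 85, 40)
        sexes = (rng.random(40) < 0.5).astype(float)
        y = 3.0 - 0.02 * ages
        res = ols_age_model(y, ages, sexes, model="M3")
        assert res.beta_age == pytest.approx(-0.02, abs=1e-12)
        assert res.p_age < 1e-12

    def test_permutation_null_rejection_rate(self, rng):
        """With y independent of age, the age t-test is calibrated:
        rejection rate at α = 0.05 within [0.03, 0.07] over 500 permutations."""
        ages = rng.uniform(19, 85, 72)
        sexes = np.r_[np.ones(32), np.zeros(40)]
        y0 = rng.normal(size=72)
        hits = 0
        for _ in range(500):
            y = rng.permutation(y0)
            if ols_age_model(y, ages, sexes, model="M3").p_age < 0.05:
                hits += 1
        assert 0.03 <= hits / 500 <= 0.07

    def test_r_t_identity_printed_form(self):
        # r = 0.5, n = 72 → t = 0.5·√70/√0.75
        r, n = 0.5, 72
        t_expected = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        # construct data with exactly that correlation
        ages = np.linspace(19, 85, n)
        z = (ages - ages.mean()) / ages.std()
        rng = np.random.default_rng(5)
        e = rng.normal(size=n)
        e -= e.mean() + z * (z @ e) / (z @ z) * 1.0  # orthogonalize to age
        y = r * z + np.sqrt(1 - r**2) * e / e.std()
        res = ols_age_model(y, ages, model="M1")
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.t_age == pytest.approx(t_expected, abs=1e-10)

    def test_model_variants_and_quadratic_term(self, rng):
        ages = rng.uniform(19, 85, 60)
        y = 1.0 + 0.01 * ages + 0.002 * ages**2 + rng.normal(0, 0.1, 60)
        res = ols_age_model(y, ages, model="M2")
        assert res.beta_age2 == pytest.approx(0.002, abs=1e-3)

    def test_sex_coding_does_not_change_age_t(self, rng):
        ages = rng.uniform(19, 85, 50)
        sexes = (rng.random(50) < 0.5).astype(float)
        y = 0.05 * ages + 0.3 * sexes + rng.normal(0, 0.5, 50)
        t01 = ols_age_model(y, ages, sexes, model="M3").t_age
        t10 = ols_age_model(y, ages, 1 - sexes, model="M3").t_age
        assert t01 == pytest.approx(t10, abs=1e-10)

    def test_constant_response_is_null(self, rng):
        ages = rng.uniform(19, 85, 30)
        res = ols_age_model(np.full(30, 2.5), ages, model="M1")
        assert res.t_age == 0.0 and res.p_age == 1.0 and res.r == 0.0

    def test_collinear_design_raises(self, rng):
        ages = np.full(30, 50.0)
        with pytest.raises(ValueError):
            ols_age_model(rng.normal(size=30), ages, model="M1")


class TestBhFdr:
    def test_hand_executed_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(100)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_step_up_property(self, pvals):
        p = np.array(pvals)
        adj = bh_fdr(p)
        assert np.all((adj >= p - 1e-15) & (adj <= 1.0))
        np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)


class TestTwoSampleT:
    def test_cohort_age_balance_statistic(self):
        """The printed male/female age summaries reproduce the reported
        two-sample t = 0.3517, p = 0.7261 (classical pooled form)."""
        t, dof, p = pooled_t_from_summary(32, 42.25, 17.99, 40, 40.75, 17.98)
        assert round(t, 4) == 0.3517
        assert round(p, 4) == 0.7261
        t_w, _, _ = welch_t_from_summary(32, 42.25, 17.99, 40, 40.75, 17.98)
        assert t_w == pytest.approx(t, abs=1e-3)

    def test_identical_groups_zero(self):
        t, _, p = welch_t_from_summary(10, 5.0, 1.0, 12, 5.0, 1.0)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_summary_equals_raw_welch(self, rng):
        a = rng.normal(3.0, 2.0, 25)
        b = rng.normal(2.5, 1.0, 30)
        t, dof, p = welch_t_from_summary(
            len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
        )
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0.0, 1.0, 10, 0.0, 1.0)
        with pytest.raises(ValueError):
            pooled_t_from_summary(5, 0.0, 0.0, 10, 0.0, 1.0)


class TestLrt:
    def test_equal_designs_null_result(self, rng):
        x = np.column_stack([np.ones(40), rng.normal(size=40)])
        stat, p = lrt_nested(rng.normal(size=40), x, x)
        assert stat == 0.0
        assert p == 1.0

    def test_null_pvalue_distribution_uniform(self, rng):
        """Adding a pure-noise column yields uniform LRT p-values."""
        n = 60
        x0 = np.column_stack([np.ones(n), rng.normal(size=n)])
        ps = []
        for _ in range(400):
            x1 = np.column_stack([x0, rng.normal(size=n)])
            y = rng.normal(size=n)
            ps.append(lrt_nested(y, x0, x1)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_true_quadratic(self, rng):
        ages = rng.uniform(19, 85, 72)
        x0 = np.column_stack([np.ones(72), ages])
        x1 = np.column_stack([np.ones(72), ages, ages**2])
        y = 0.01 * ages + 0.003 * ages**2 + rng.normal(0, 0.5, 72)
        stat, p = lrt_nested(y, x0, x1)
        assert p < 0.001

    def test_non_nested_rejected(self, rng):
        x0 = np.column_stack([np.ones(30), rng.normal(size=30)])
        x1 = np.column_stack([np.ones(30), rng.normal(size=30)])
        with pytest.raises(ValueError, match="nested"):
            lrt_nested(rng.normal(size=30), x0, x1)


class TestVertexwise:
    def test_null_cohort_false_positive_fraction(self, rng):
        ages = rng.uniform(19, 85, 72)
        sexes = np.r_[np.ones(32), np.zeros(40)]
        maps = rng.normal(size=(72, 300))
        out = vertexwise_regression(maps, ages, sexes)
        assert out["significant"].mean() <= 0.05

    def test_localized_effect_detected(self, rng):
        ages = rng.uniform(19, 85, 72)
        sexes = np.r_[np.ones(32), np.zeros(40)]
        maps = rng.normal(size=(72, 200))
        truth = np.zeros(200, dtype=bool)
        truth[40:80] = True
        maps[:, truth] += np.outer(0.08 * (ages - ages.mean()), np.ones(40))
        out = vertexwise_regression(maps, ages, sexes)
        sig = out["significant"]
        jaccard = (sig & truth).sum() / max((sig | truth).sum(), 1)
        assert jaccard > 0.5

    def test_constant_metric_gives_zero_r(self, rng):
        ages = rng.uniform(19, 85, 30)
        maps = np.ones((30, 50))
        out = vertexwise_regression(maps, ages, model="M1")
        assert np.all(out["r"] == 0.0)
        assert np.all(out["p"] == 1.0)

    def test_matches_per_vertex_ols(self, rng):
        ages = rng.uniform(19, 85, 40)
        sexes = (rng.random(40) < 0.5).astype(float)
        maps = rng.normal(size=(40, 10))
        out = vertexwise_regression(maps, ages, sexes)
        for v in range(10):
            res = ols_age_model(maps[:, v], ages, sexes, model="M3")
            assert out["t"][v] == pytest.approx(res.t_age, abs=1e-10)
            assert out["r"][v] == pytest.approx(res.r, abs=1e-12)

    def test_subject_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            vertexwise_regression(rng.normal(size=(10, 5)), np.arange(12))


class TestSpatialCorrelation:
    def test_self_negation_and_bruteforce(self, rng):
        a = rng.normal(size=120)
        b = rng.normal(size=120)
        r, p, sig = spatial_correlation_matrix({"a": a, "na": -a, "b": b})
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "na"] == pytest.approx(-1.0)
        assert r.loc["a", "b"] == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)

    def test_pairwise_missing_exclusion(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(0, 0.1, 50)
        b_miss = b.copy()
        b_miss[:10] = np.nan
        r, _, _ = spatial_correlation_matrix({"a": a, "b": b_miss})
        expected = np.corrcoef(a[10:], b[10:])[0, 1]
        assert r.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_common_vertices(self):
        a = np.array([1.0, 2.0, np.nan, np.nan])
        b = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            spatial_correlation_matrix({"a": a, "b": b})


class TestRoiSummary:
    LABELS = np.array([1] * 5 + [2] * 5)

    def test_uniform_and_two_roi_maps(self):
        maps = np.vstack([np.full(10, 3.0), np.r_[np.full(5, 1.0), np.full(5, 9.0)]])
        df = roi_summary(maps, self.LABELS, {1: "A", 2: "B"})
        assert df.loc[0, "A"] == 3.0 and df.loc[0, "B"] == 3.0
        assert df.loc[1, "A"] == 1.0 and df.loc[1, "B"] == 9.0

    def test_unweighted_vs_area_weighted_difference(self):
        """Documents the unweighted-mean convention: on a fixture with skewed
        per-vertex areas the two conventions differ by the analytic amount."""
        values = np.array([1.0, 1.0, 1.0, 5.0, 5.0])
        areas = np.array([1.0, 1.0, 1.0, 3.0, 3.0])
        labels = np.ones(5, dtype=int)
        unweighted = roi_summary(values[None, :], labels).iloc[0, 0]
        weighted = float(np.sum(values * areas) / areas.sum())
        assert unweighted == pytest.approx(values.mean())
        assert weighted - unweighted == pytest.approx(
            (5.0 - 1.0) * (6.0 / 9.0 - 2.0 / 5.0), abs=1e-12
        )

    def test_nan_vertices_ignored(self):
        maps = np.array([[1.0, np.nan, 3.0, np.nan, np.nan, 4.0, 4.0, 4.0, 4.0, 4.0]])
        df = roi_summary(maps, self.LABELS)
        assert df.iloc[0, 0] == pytest.approx(2.0)

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            roi_summary(np.ones((1, 4)), self.LABELS)
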