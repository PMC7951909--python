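import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import jzs_bf10_bruteforce
from mriq.phantoms import simulate_lmm_table
from mriq.stats import (
    StatsError,
    bf_evidence_label,
    fit_lmm_age,
    jzs_bf_ttest,
    paired_ttest,
    reliability_bf_anova,
    resample_age_analysis,
    sample_interval_ages,
    scan_time_regression,
    slab_vs_wholebrain_test,
)


class TestPairedTTest:
    def test_identical_pairs(self, rng):
        x = rng.normal(size=10)
        res = paired_ttest(x, x.copy())
        assert res.t == 0.0 and res.p == 1.0 and res.bf10 < 1

    def test_balanced_differences_give_zero_t(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        res = paired_ttest(x, y)
        assert res.t == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(5, 2, 30)
        y = rng.normal(4, 2, 30)
        res = paired_ttest(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(30))
        p_oracle = 2 * scipy.stats.t.sf(abs(t_oracle), 29)
        assert res.t == pytest.approx(t_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)
        assert res.df == 29

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(StatsError, match="zero variance with a nonzero mean"):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError, match="at least 2 pairs"):
            paired_ttest([1.0], [2.0])


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bf_ttest(0.0, 15) < 1

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf_ttest(t, 15) for t in np.linspace(0, 6, 25)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert jzs_bf_ttest(-3.0, 15) == pytest.approx(jzs_bf_ttest(3.0, 15), rel=1e-9)

    def test_null_evidence_grows_with_n(self):
        bfs = [jzs_bf_ttest(0.0, n) for n in (10, 100, 1000, 10_000)]
        assert all(b2 < b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t", [0.0, 0.5, 1.0, 2.0, 3.5, 5.0])
    @pytest.mark.parametrize("n", [5, 15, 50])
    def test_quadrature_matches_bruteforce_grid(self, t, n):
        ours = jzs_bf_ttest(t, n)
        oracle = jzs_bf10_bruteforce(t, n_eff=n, df=n - 1)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(StatsError, match="n >= 2"):
            jzs_bf_ttest(1.0, 1)


class TestScanTimeRegression:
    def test_collinear_points_fit_exactly(self):
        df = pd.DataFrame({"scan_time_s": [100, 200, 300, 400], "y": [1.0, 2.0, 3.0, 4.0]})
        res = scan_time_regression(df, "y")
        assert res.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-10

    def test_bonferroni_threshold(self):
        df = pd.DataFrame({"scan_time_s": [1, 2, 3], "y": [1.0, 2.1, 2.9]})
        res = scan_time_regression(df, "y", family_alpha=0.05, n_models=2)
        assert res.bonferroni_alpha == 0.025

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(100, 3000, 40)
        y = 2.0 * x + rng.normal(0, 50, 40)
        df = pd.DataFrame({"scan_time_s": x, "y": y})
        res = scan_time_regression(df, "y")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-8, abs=1e-8)
        assert res.slope == pytest.approx(beta[1], rel=1e-8)
        se = math.sqrt(
            (np.sum((y - X @ beta) ** 2) / 38) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert abs(res.slope - 2.0) < 3 * se

    def test_degenerate_predictor_rejected(self):
        df = pd.DataFrame({"scan_time_s": [5, 5, 5], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(StatsError, match="not identifiable"):
            scan_time_regression(df, "y")

    def test_missing_scan_times_excluded(self):
        df = pd.DataFrame(
            {"scan_time_s": [1, 2, 3, np.nan], "y": [1.0, 2.0, 3.0, 99.0]}
        )
        assert scan_time_regression(df, "y").n == 3


class TestLmmAge:
    def test_constant_age_degenerates_to_null(self):
        tab = simulate_lmm_table(4, 10, 1.0, 2.0, 0.0, seed=2)
        tab["age"] = 44.0
        comp = fit_lmm_age(tab, response="response")
        assert comp.chi2 == 0.0 and comp.p_lrt == 1.0
        assert comp.fit_warnings

    def test_slope_recovered_with_informative_data(self):
        tab = simulate_lmm_table(20, 15, 2.0, 3.0, -0.3, seed=5)
        comp = fit_lmm_age(tab, response="response")
        lo, hi = comp.ci95
        assert lo < -0.3 < hi
        assert comp.p_lrt < 1e-6
        assert comp.bf10_bic > 10

    def test_direction_agreement_bic_vs_lrt(self):
        for seed in range(5):
            tab = simulate_lmm_table(10, 8, 1.5, 3.0, 0.0, seed=seed)
            comp = fit_lmm_age(tab, response="response")
            assert comp.chi2 >= 0.0
            assert (comp.bf10_bic > 1) == (comp.bic_full < comp.bic_null)

    def test_single_database_rejected(self):
        tab = simulate_lmm_table(1, 10, 1.0, 2.0, 0.0, seed=0)
        with pytest.raises(StatsError, match="at least 2 databases"):
            fit_lmm_age(tab, response="response")

    def test_interval_ages_must_be_resolved_first(self):
        tab = simulate_lmm_table(3, 5, 1.0, 2.0, 0.0, seed=0)
        tab.loc[0, "age"] = np.nan
        with pytest.raises(StatsError, match="sample_interval_ages"):
            fit_lmm_age(tab, response="response")


class TestIntervalAges:
    def frame(self, n=5):
        return pd.DataFrame(
            {
                "age": [np.nan] * n + [40.0],
                "age_min": [20.0] * n + [np.nan],
                "age_max": [25.0] * n + [np.nan],
            }
        )

    def test_degenerate_interval(self):
        df = pd.DataFrame({"age": [np.nan], "age_min": [20.0], "age_max": [20.0]})
        out = sample_interval_ages(df, np.random.default_rng(0))
        assert out.loc[0, "age"] == 20.0

    def test_uniform_mean(self):
        df = pd.DataFrame(
            {"age": [np.nan] * 100_000, "age_min": 20.0, "age_max": 25.0}
        )
        out = sample_interval_ages(df, np.random.default_rng(1))
        assert out["age"].mean() == pytest.approx(22.5, abs=0.02)
        assert out["age"].between(20, 25).all()

    def test_point_ages_untouched_and_deterministic(self):
        df = self.frame()
        a = sample_interval_ages(df, np.random.default_rng(3))
        b = sample_interval_ages(df, np.random.default_rng(3))
        assert a["age"].iloc[-1] == 40.0
        assert a["age"].equals(b["age"])


class TestResampleAgeAnalysis:
    def cohort_frame(self, interval_width=5.0, seed=4):
        tab = simulate_lmm_table(8, 10, 2.0, 3.0, -0.3, seed=seed)
        tab["age_min"] = np.nan
        tab["age_max"] = np.nan
        mask = tab["database"] == "db00"
        tab.loc[mask, "age_min"] = tab.loc[mask, "age"] - interval_width / 2
        tab.loc[mask, "age_max"] = tab.loc[mask, "age"] + interval_width / 2
        tab.loc[mask, "age"] = np.nan
        return tab

    def test_no_intervals_is_a_contract_error(self):
        tab = simulate_lmm_table(3, 5, 1.0, 2.0, 0.0, seed=0)
        tab["age_min"] = np.nan
        tab["age_max"] = np.nan
        with pytest.raises(StatsError, match="use fit_lmm_age"):
            resample_age_analysis(tab, response="response", n_iter=3)

    def test_degenerate_intervals_collapse_to_single_fit(self):
        tab = self.cohort_frame(interval_width=0.0)
        summary = resample_age_analysis(tab, response="response", n_iter=5, seed=9)
        assert np.ptp(summary.p_values) == 0.0
        resolved = sample_interval_ages(tab, np.random.default_rng(0))
        single = fit_lmm_age(resolved, response="response")
        assert summary.mean_p == pytest.approx(single.p_lrt, abs=1e-12)

    def test_reduced_iterations_self_consistent(self):
        tab = self.cohort_frame()
        small = resample_age_analysis(tab, response="response", n_iter=15, seed=1)
        large = resample_age_analysis(tab, response="response", n_iter=60, seed=2)
        mc_se = large.p_values.std(ddof=1) * math.sqrt(1 / 15 + 1 / 60)
        assert abs(small.mean_p - large.mean_p) < 4 * max(mc_se, 1e-6)
        assert small.n_iter == 15 and len(small.p_values) == 15


class TestSlabVsWholebrain:
    def test_known_shift_detected(self, rng):
        base = rng.normal(30, 2, 15)
        slab = {f"s{i}": base[i] + 10 for i in range(15)}
        whole = {f"s{i}": base[i] + rng.normal(0, 0.5) for i in range(15)}
        res = slab_vs_wholebrain_test(slab, whole)
        assert res.t > 0 and res.bf10 > 1

    def test_unpaired_subjects_dropped_with_warning(self, rng):
        slab = {f"s{i}": float(i) for i in range(5)}
        whole = {f"s{i}": float(i) + rng.normal(0, 1) for i in range(1, 6)}
        with pytest.warns(UserWarning, match="unpaired"):
            res = slab_vs_wholebrain_test(slab, whole)
        assert res.n == 4

    def test_single_pair_rejected(self):
        with pytest.raises(StatsError, match=">= 2 complete"):
            slab_vs_wholebrain_test({"a": 1.0}, {"a": 2.0})


class TestReliabilityBayesianAnova:
    def test_identical_groups_favour_null(self, rng):
        a = rng.normal(10, 2, 15)
        res = reliability_bf_anova(a, a.copy())
        assert res.bf10 < 1

    def test_separated_groups_favour_effect(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(5, 1, 15)
        res = reliability_bf_anova(a, b)
        assert res.bf10 > 10

    def test_matches_bruteforce_oracle(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 20)
        res = reliability_bf_anova(a, b)
        n_eff = 12 * 20 / 32
        oracle = jzs_bf10_bruteforce(res.t, n_eff=n_eff, df=30)
        assert res.bf10 == pytest.approx(oracle, rel=1e-4)

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(StatsError, match="n >= 2"):
            reliability_bf_anova([1.0], rng.normal(size=5))


def test_evidence_labels_span_jeffreys_bands():
    assert bf_evidence_label(1.5) == "anecdotal evidence for H1"
    assert bf_evidence_label(5) == "moderate evidence for H1"
    assert bf_evidence_label(20) == "strong evidence for H1"
    assert bf_evidence_label(50) == "very strong evidence for H1"
    assert bf_evidence_label(500) == "extreme evidence for H1"
    assert bf_evidence_label(1 / 20) == "strong evidence for H0"
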