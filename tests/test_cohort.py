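import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octplaque import (
    CohortSpec,
    StatsConfig,
    compare_groups,
    multivariate_logistic,
    roc_analysis,
    run_pipeline,
    simulate_cohort,
    spearman_prune,
    univariate_logistic,
)
from octplaque.io import write_report


def two_by_two_table(a, b, c, d, feature="x", outcome="CV death"):
    """Binary predictor/outcome cohort with counts: exposed cases a,
    exposed controls b, unexposed cases c, unexposed controls d."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({feature: x, outcome: y})


class TestCompareGroups:
    def test_identical_groups_no_difference(self):
        base = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        table = pd.concat([base.assign(**{"CV death": 0}), base.assign(**{"CV death": 1})])
        (row,) = compare_groups(table)
        assert row.p_value == pytest.approx(1.0)

    def test_shifted_groups_strongly_different(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 0.01, 30)
        table = pd.DataFrame(
            {"f": np.r_[x0, x0 + 10.0], "CV death": np.r_[np.zeros(30), np.ones(30)]}
        )
        (row,) = compare_groups(table)
        assert row.p_value < 0.001

    def test_cholesterol_crystal_contingency(self):
        """A 17/7 vs 12/68 split of a binary flag between 24 events and 80
        non-events is overwhelmingly significant by chi-square."""
        table = two_by_two_table(17, 12, 7, 68, feature="Cholesterol Crystal")
        (row,) = compare_groups(table)
        assert row.kind == "categorical"
        assert row.p_value < 0.001
        assert row.summary_pos.startswith("17 (70.8%)")

    def test_welch_flag_changes_test(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "f": np.r_[rng.normal(0, 1, 40), rng.normal(0.5, 5, 15)],
                "CV death": np.r_[np.zeros(40), np.ones(15)],
            }
        )
        p_pooled = compare_groups(table)[0].p_value
        p_welch = compare_groups(table, config=StatsConfig(welch=True))[0].p_value
        assert p_pooled != p_welch


class TestSpearmanPrune:
    def make_table(self, rng, n=200):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        return pd.DataFrame({"a": a, "b": b, "CV death": y})

    def test_exact_copy_pruned(self):
        rng = np.random.default_rng(0)
        table = self.make_table(rng)
        table["a_copy"] = table["a"]
        res = spearman_prune(table)
        assert ("a" in res.retained) ^ ("a_copy" in res.retained)
        assert len(res.dropped) == 1

    def test_independent_features_both_retained(self):
        rng = np.random.default_rng(42)
        res = spearman_prune(self.make_table(rng, n=500))
        assert set(res.retained) == {"a", "b"}

    def test_monotone_transform_pruned_rank_invariance(self):
        rng = np.random.default_rng(3)
        table = self.make_table(rng)
        table["a_exp"] = np.exp(table["a"])
        res = spearman_prune(table)
        assert res.correlation.loc["a", "a_exp"] == pytest.approx(1.0)
        assert ("a" in res.retained) ^ ("a_exp" in res.retained)

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        table = self.make_table(rng)
        table["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_prune(table)
        assert "const" not in res.correlation.columns

    def test_column_permutation_invariant(self):
        # near-duplicate (not an exact tie) so the keep rule has a
        # unique winner regardless of column order
        rng = np.random.default_rng(5)
        table = self.make_table(rng)
        table["a_near"] = table["a"] + 1e-4 * rng.normal(size=len(table))
        res1 = spearman_prune(table)
        shuffled = table[["a_near", "b", "a", "CV death"]]
        res2 = spearman_prune(shuffled)
        assert set(res1.retained) == set(res2.retained)


class TestUnivariateLogistic:
    def test_binary_predictor_matches_cross_product_ratio(self):
        table = two_by_two_table(10, 10, 5, 20)
        (res,) = univariate_logistic(table, ["x"])
        assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)

    def test_null_predictor_odds_ratio_near_one(self):
        rng = np.random.default_rng(0)
        n = 1000
        table = pd.DataFrame(
            {"x": rng.normal(size=n), "CV death": rng.permutation([1] * 250 + [0] * 750)}
        )
        (res,) = univariate_logistic(table, ["x"])
        assert 0.8 <= res.odds_ratio <= 1.25

    def test_perfect_predictor_flags_separation(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        table = pd.DataFrame({"x": y.copy(), "CV death": y})
        (res,) = univariate_logistic(table, ["x"])
        assert res.separated
        assert np.isinf(res.ci_high) or np.isinf(res.odds_ratio)

    def test_wald_ci_brackets_estimate(self):
        table, _ = simulate_cohort(CohortSpec(seed=2))
        for res in univariate_logistic(table, ["FC Surface area-T (mm^2)"]):
            assert res.ci_low <= res.odds_ratio <= res.ci_high
            assert res.odds_ratio > 0


class TestMultivariateLogistic:
    def test_single_feature_reduces_to_univariate(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.5 * x - 0.5))))
        table = pd.DataFrame({"x": x, "CV death": y})
        (uni,) = univariate_logistic(table, ["x"])
        multi = multivariate_logistic(table, ["x"])
        assert multi.loc["x", "coef"] == pytest.approx(uni.coef, abs=1e-8)
        assert multi.loc["x", "p_value"] == pytest.approx(uni.p_value, abs=1e-8)

    def test_parameter_recovery_two_predictors(self):
        """A generative beta of (0.7, 0) on orthogonal predictors is covered
        by the Wald 95% CI in at least 85% of seeded replicates."""
        covered = np.zeros(2)
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x1, x2 = rng.normal(size=2000), rng.normal(size=2000)
            p = 1 / (1 + np.exp(-(-1.0 + 0.7 * x1 + 0.0 * x2)))
            table = pd.DataFrame({"x1": x1, "x2": x2, "CV death": rng.binomial(1, p)})
            multi = multivariate_logistic(table, ["x1", "x2"])
            for i, (name, beta) in enumerate([("x1", 0.7), ("x2", 0.0)]):
                lo = np.log(multi.loc[name, "ci_low"])
                hi = np.log(multi.loc[name, "ci_high"])
                covered[i] += lo <= beta <= hi
        assert (covered >= 0.85 * n_rep).all()

    def test_duplicated_predictor_rank_deficiency(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": rng.normal(size=100)})
        table["x_dup"] = table["x"]
        table["CV death"] = rng.integers(0, 2, 100)
        with pytest.raises(ValueError, match="rank deficient"):
            multivariate_logistic(table, ["x", "x_dup"])

    def test_low_events_per_variable_warns(self):
        table, _ = simulate_cohort(CohortSpec(seed=3))
        cols = ["Lesion length (mm)", "Maximum calcium angle (°)", "Maximum FC angle (°)"]
        with pytest.warns(UserWarning, match="events-per-variable"):
            multivariate_logistic(table, cols)


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis(np.array([2.0, 3.0, 0.0, 1.0]), np.array([1, 1, 0, 0]), n_boot=200)
        assert res.auc == 1.0
        assert res.optimal_cutoff == 2.0
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0

    def test_all_ties_give_half(self):
        res = roc_analysis(np.ones(40), np.r_[np.ones(20), np.zeros(20)], n_boot=200)
        assert res.auc == 0.5

    def test_youden_cutoff_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(20, 80))
            scores = np.round(rng.normal(size=n), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            res = roc_analysis(scores, y, n_boot=200, seed=0)
            best = (-np.inf, None)
            for thr in sorted(set(scores)):
                pred = scores >= thr
                j = pred[y == 1].mean() + (~pred)[y == 0].mean()
                if j > best[0] + 1e-12:
                    best = (j, thr)
            assert res.optimal_cutoff == best[1]
            assert res.sensitivity_at_cutoff + res.specificity_at_cutoff == pytest.approx(best[0])

    @settings(max_examples=25, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_auc_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=60)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        a1 = roc_analysis(scores, y, n_boot=200, seed=0).auc
        a2 = roc_analysis(np.exp(scale * scores) + shift, y, n_boot=200, seed=0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_bootstrap_ci_narrows_with_n(self):
        widths = {}
        for n in (100, 1000):
            rng = np.random.default_rng(29)
            scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            y = np.r_[np.ones(n, int), np.zeros(n, int)]
            res = roc_analysis(scores, y, n_boot=500, seed=1)
            widths[n] = res.ci_high - res.ci_low
        assert widths[1000] < widths[100]

    def test_auc_matches_reference_implementation(self):
        """The rank-based Mann–Whitney AUC agrees with scikit-learn's
        trapezoidal ROC integration, including under heavy ties."""
        from sklearn.metrics import roc_auc_score

        from octplaque.cohort import mann_whitney_auc

        rng = np.random.default_rng(31)
        for _ in range(10):
            scores = np.round(rng.normal(size=200), 1)  # force ties
            y = rng.integers(0, 2, size=200)
            if y.min() == y.max():
                continue
            ours = mann_whitney_auc(scores[y == 1], scores[y == 0])
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(10.0), np.ones(10, int), n_boot=200)


class TestRunPipeline:
    def test_deterministic_report_bytes(self, tmp_path):
        table, _ = simulate_cohort(CohortSpec(seed=5))
        cfg = StatsConfig(seed=5, n_boot=300)
        for name in ("a.json", "b.json"):
            write_report(run_pipeline(table, cfg), tmp_path / name)
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_report_shape(self):
        table, _ = simulate_cohort(CohortSpec(seed=5))
        report = run_pipeline(table, StatsConfig(seed=5, n_boot=300))
        assert report["header"]["n_lesions"] == 104
        assert len(report["group_comparison"]) == 31
        assert report["pruning"]["n_retained"] + len(report["pruning"]["dropped"]) == 31
        assert json.dumps  # report must serialize
        json.dumps(report, default=float)

    def test_large_cohort_recovers_fc_surface_area_signal(self):
        """With ample power, every multivariate-significant feature belongs
        to the severity-driven family, and the fibrous-cap surface-area
        cluster scores a high AUC (the generative outcome driver)."""
        table, truth = simulate_cohort(CohortSpec(n_patients=800, seed=1))
        report = run_pipeline(table, StatsConfig(seed=1, n_boot=300))
        sig = report["multivariate"]["significant"]
        assert sig, "expected at least one multivariate-significant feature"
        null_family = {
            "Minimum lumen area (mm^2)",
            "Average lumen area (mm^2)",
            "Minimum lumen diameter (mm)",
            "Average lumen diameter (mm)",
            "Minimum FC thickness (mm)",
        }
        assert not (set(sig) & null_family)
        res = roc_analysis(
            table["FC Surface area-T (mm^2)"].to_numpy(),
            table["CV death"].to_numpy(),
            n_boot=300,
            seed=1,
        )
        # an odds ratio of 2.38 per SD of a log-normal score implies a
        # moderately discriminative marginal AUC (~0.68)
        assert res.auc > 0.6
        assert res.ci_low > 0.55

    def test_missing_outcome_column_rejected(self):
        table, _ = simulate_cohort(CohortSpec(seed=5))
        with pytest.raises(ValueError, match="outcome"):
            run_pipeline(table.drop(columns=["CV death"]), StatsConfig())

    def test_single_class_outcome_rejected(self):
        table, _ = simulate_cohort(CohortSpec(seed=5))
        table["CV death"] = 0
        with pytest.raises(ValueError, match="single class"):
            run_pipeline(table, StatsConfig())
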