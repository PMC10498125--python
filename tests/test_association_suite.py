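import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from kifscore import association_suite as assoc
from kifscore import setscore_engine as se


class TestBhAdjustment:
    def test_textbook_oracle_on_five_pvalues(self):
        # manual BH: sort, p*(m/rank), enforce monotonicity from the largest
        p = np.array([0.01, 0.04, 0.03, 0.20, 0.50])
        adj = assoc.bh_adjust(p)
        expected = np.array([0.05, 0.0666666667, 0.0666666667, 0.25, 0.50])
        assert adj == pytest.approx(expected)

    def test_adjusted_never_below_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = assoc.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestScorePrognosis:
    def test_planted_effect_yields_risk_label(self, small_bundle):
        spec = small_bundle.spec
        scores = se.compute_kifscore(
            small_bundle.expression, spec.positive_truth, spec.negative_truth,
            cohorts=small_bundle.clinical.set_index("sample")["cohort"],
        )
        prog = assoc.score_prognosis(scores, small_bundle.clinical, endpoint="OS")
        assert (prog["hr"] > 1).all()
        assert (prog["p"] < 0.05).all()
        assert (prog["label"] == "risk").all()

    def test_shuffled_score_is_null(self, small_bundle):
        rng = np.random.default_rng(1)
        spec = small_bundle.spec
        scores = se.compute_kifscore(
            small_bundle.expression, spec.positive_truth, spec.negative_truth,
            cohorts=small_bundle.clinical.set_index("sample")["cohort"],
        )
        covered = 0
        for _ in range(100):
            shuffled = scores.copy()
            shuffled["kifscore"] = rng.permutation(shuffled["kifscore"].to_numpy())
            prog = assoc.score_prognosis(shuffled, small_bundle.clinical, per_cohort=False)
            covered += prog.loc[0, "ci_low"] <= 1.0 <= prog.loc[0, "ci_high"]
        assert covered >= 90


class TestKmLogrank:
    def test_survival_starts_at_one_and_identical_groups_are_null(self):
        times = np.array([5.0, 8.0, 12.0, 20.0] * 2)
        events = np.array([1, 1, 0, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        curves, rec = assoc.km_logrank(times, events, groups)
        for curve in curves.values():
            assert curve.iloc[0, 0] == pytest.approx(1.0)
        assert rec.estimate == pytest.approx(0.0, abs=1e-12)
        assert rec.p > 0.99

    def test_complete_separation_is_significant(self):
        times = np.concatenate([np.arange(1, 11), np.arange(101, 111)]).astype(float)
        events = np.ones(20)
        groups = np.array(["early"] * 10 + ["late"] * 10)
        _, rec = assoc.km_logrank(times, events, groups)
        assert rec.p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            assoc.km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestAdjustedLinear:
    def _covariates(self, n, rng):
        return pd.DataFrame(
            {"age": rng.normal(60, 10, n),
             "sex": rng.choice(["female", "male"], n),
             "race": rng.choice(["groupA", "groupB"], n)},
            index=[f"S{i}" for i in range(n)],
        )

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(2)
        n = 50
        idx = [f"S{i}" for i in range(n)]
        score = pd.Series(rng.normal(size=n), index=idx)
        rec = assoc.adjusted_linear_assoc(score, 2.0 * score, self._covariates(n, rng))
        assert rec.estimate == pytest.approx(2.0, abs=1e-8)
        assert rec.p < 1e-12

    def test_constant_covariate_raises_naming_column(self):
        rng = np.random.default_rng(3)
        n = 30
        idx = [f"S{i}" for i in range(n)]
        score = pd.Series(rng.normal(size=n), index=idx)
        cov = pd.DataFrame({"age": np.full(n, 60.0)}, index=idx)
        with pytest.raises(ValueError, match="age"):
            assoc.adjusted_linear_assoc(score, 2 * score, cov)

    def test_null_association_type_one_error(self):
        rng = np.random.default_rng(4)
        n = 60
        rejections = 0
        for _ in range(100):
            idx = [f"S{i}" for i in range(n)]
            score = pd.Series(rng.normal(size=n), index=idx)
            burden = pd.Series(rng.normal(size=n), index=idx)
            rec = assoc.adjusted_linear_assoc(score, burden, self._covariates(n, rng))
            rejections += rec.p < 0.05
        assert rejections <= 10


class TestSpearmanPanel:
    def test_rank_transform_of_score_gives_rho_one(self):
        rng = np.random.default_rng(5)
        idx = [f"S{i}" for i in range(30)]
        score = pd.Series(rng.normal(size=30), index=idx)
        feats = pd.DataFrame({"ranked": score.rank()}, index=idx)
        panel = assoc.spearman_panel(score, feats)
        assert panel.loc[0, "estimate"] == pytest.approx(1.0)

    def test_constant_feature_reported_missing_with_warning(self, caplog):
        idx = ["S0", "S1", "S2", "S3"]
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        feats = pd.DataFrame({"flat": [5.0] * 4, "ok": [1.0, 3.0, 2.0, 4.0]}, index=idx)
        with caplog.at_level("WARNING", logger="kifscore"):
            panel = assoc.spearman_panel(score, feats)
        assert "flat" in caplog.text
        assert np.isnan(panel.set_index("target").loc["flat", "estimate"])
        assert np.isfinite(panel.set_index("target").loc["ok", "p"])

    def test_too_few_paired_observations_rejected(self):
        score = pd.Series([1.0, 2.0], index=["S0", "S1"])
        feats = pd.DataFrame({"f": [1.0, 2.0]}, index=["S0", "S1"])
        with pytest.raises(ValueError, match="fewer than 3"):
            assoc.spearman_panel(score, feats)

    def test_planted_correlations_recovered(self, small_bundle):
        spec = small_bundle.spec
        scores = se.compute_kifscore(
            small_bundle.expression, spec.positive_truth, spec.negative_truth,
            cohorts=small_bundle.clinical.set_index("sample")["cohort"],
        ).set_index("sample")["kifscore"]
        panel = assoc.spearman_panel(scores, small_bundle.features).set_index("target")
        for entry in spec.feature_plan:
            assert np.sign(panel.loc[entry.name, "estimate"]) == np.sign(entry.spearman)


class TestGroupTests:
    def test_identical_groups_are_null(self):
        vals = np.concatenate([np.arange(10.0)] * 2)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        assert assoc.group_tests(vals, labels, kind="wilcoxon").p > 0.9
        three = np.concatenate([np.arange(10.0)] * 3)
        labels3 = np.repeat(["a", "b", "c"], 10)
        assert assoc.group_tests(three, labels3, kind="kruskal").p > 0.9

    def test_fisher_perfect_association_matches_hypergeometric(self):
        rec = assoc.group_tests(None, kind="fisher", table=[[10, 0], [0, 10]])
        assert rec.p == pytest.approx(2.0 / comb(20, 10, exact=True), rel=1e-9)
        assert rec.p < 0.001

    def test_fisher_requires_two_by_two(self):
        with pytest.raises(ValueError, match="2x2"):
            assoc.group_tests(None, kind="fisher", table=[[1, 2, 3], [4, 5, 6]])

    def test_paired_wilcoxon_detects_systematic_shift(self):
        rng = np.random.default_rng(6)
        tumor = rng.normal(1.0, 0.3, size=20)
        adjacent = tumor - 0.8 + rng.normal(0, 0.1, size=20)
        rec = assoc.group_tests((tumor, adjacent), kind="paired_wilcoxon")
        assert rec.p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            assoc.group_tests(np.arange(5.0), np.array(["a"] * 5), kind="wilcoxon")

    def test_empty_paired_arrays_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            assoc.group_tests((np.array([]), np.array([])), kind="paired_wilcoxon")


class TestDifferentialFilter:
    def _matrix(self, rng, n_genes=10, n_per_group=20):
        cols = [f"H{i}" for i in range(n_per_group)] + [f"L{i}" for i in range(n_per_group)]
        expr = pd.DataFrame(
            rng.normal(size=(n_genes, 2 * n_per_group)),
            index=[f"G{i}" for i in range(n_genes)], columns=cols,
        )
        groups = pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=cols)
        return expr, groups

    def test_identical_means_select_nothing(self):
        rng = np.random.default_rng(7)
        expr, groups = self._matrix(rng)
        out = assoc.differential_filter(expr, groups)
        assert not out["selected"].any()

    def test_constructed_separation_selects_only_the_shifted_gene(self):
        rng = np.random.default_rng(8)
        expr, groups = self._matrix(rng)
        expr = expr * 0.1  # sd 0.1 noise
        expr.loc["G3", groups == "high"] += 2.0
        out = assoc.differential_filter(expr, groups, lfc_cut=1.0, padj_cut=0.05)
        assert list(out.loc[out["selected"], "gene"]) == ["G3"]
        assert out.set_index("gene").loc["G3", "log2fc"] == pytest.approx(2.0, abs=0.2)

    def test_output_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        expr, groups = self._matrix(rng)
        out1 = assoc.differential_filter(expr, groups)
        perm = list(rng.permutation(expr.columns))
        out2 = assoc.differential_filter(expr[perm], groups[perm])
        pd.testing.assert_frame_equal(out1, out2)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(10)
        expr, groups = self._matrix(rng, n_per_group=2)
        groups.iloc[0] = "low"
        with pytest.raises(ValueError, match="at least 2"):
            assoc.differential_filter(expr, groups)
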