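"""AUC, nested resampling, model comparison, importance, subgroup guard
and the univariate statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ftvmorph.evaluate import (EvalResult, LearnerSpec, OmissionNotice,
                               ResamplingPlan, auc, compare_models,
                               default_grid, fisher_exact_rxc, nested_cv,
                               select_optimal, spearman_ftv_correlations,
                               subgroup_eval, univariate_report,
                               variable_importance)

FAST = {fam: tuple(default_grid(fam, "fast"))
        for fam in ("elastic_net", "cart", "random_forest", "gbm")}


class TestAuc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([1, 0, 1, 0], [1, 0, 1, 0], 1.0),            # perfect ranking
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),    # all ties
        ([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0], 0.75),   # 3 of 4 pairs concordant
    ])
    def test_worked_examples(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_equals_brute_force_pair_counting(self):
        """Rank-based AUC equals exhaustive concordant-pair counting
        (ties at 1/2) on random score tables."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(brute)
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores))


def _separable_table(n=80, p_noise=4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    df = pd.DataFrame(rng.normal(size=(n, p_noise)),
                      columns=[f"noise{j}" for j in range(p_noise)])
    df["signal"] = y.astype(float)
    df["label"] = y
    return df


class TestNestedCv:
    @pytest.mark.parametrize("family", list(FAST))
    def test_separable_table_scores_perfectly(self, family):
        table = _separable_table()
        plan = ResamplingPlan(n_outer=5, seed=1)
        res = nested_cv(table, LearnerSpec(family, FAST[family], 1), plan)
        assert res.mean_auc == pytest.approx(1.0)

    def test_rerun_is_bit_identical(self):
        table = _separable_table(seed=3)
        table["signal"] += np.random.default_rng(4).normal(0, 1.0, len(table))
        plan = ResamplingPlan(n_outer=6, seed=5)
        spec = LearnerSpec("random_forest", FAST["random_forest"], 5)
        r1 = nested_cv(table, spec, plan)
        r2 = nested_cv(table, spec, plan)
        assert np.array_equal(r1.aucs, r2.aucs)
        assert r1.chosen_params == r2.chosen_params

    def test_outer_test_sets_are_stratified_within_one(self):
        from sklearn.model_selection import train_test_split
        table = _separable_table(n=120, seed=6)
        y = table["label"].to_numpy()
        share = y.mean() * 30  # test fraction 0.25 of 120
        for i in range(20):
            _, _, _, y_te = train_test_split(
                table.drop(columns="label"), y, test_size=0.25,
                stratify=y, random_state=7 + i)
            assert abs(y_te.sum() - share) <= 1

    def test_too_few_positives_rejected(self):
        table = _separable_table(n=40)
        table["label"] = 0
        table.loc[table.index[:5], "label"] = 1
        with pytest.raises(ValueError, match="positives"):
            nested_cv(table, LearnerSpec("cart", FAST["cart"], 0),
                      ResamplingPlan(n_outer=2, seed=0))


class TestSelectOptimal:
    def _result(self, family, aucs):
        return EvalResult(family, "with_shape", np.asarray(aucs), [])

    def test_highest_mean_wins(self):
        results = [self._result("elastic_net", [0.64] * 20),
                   self._result("cart", [0.60] * 20),
                   self._result("random_forest", [0.58] * 20),
                   self._result("gbm", [0.55] * 20)]
        assert select_optimal(results).family == "elastic_net"

    def test_mean_tie_broken_by_lower_sd(self):
        a = self._result("cart", [0.5, 0.75] * 10)
        b = self._result("gbm", [0.25, 1.0] * 10)
        assert select_optimal([a, b]).family == "cart"

    def test_single_candidate_returned(self):
        r = self._result("gbm", [0.5] * 20)
        assert select_optimal([r]) is r

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            select_optimal([])


class TestCompareModels:
    def _res(self, aucs):
        return EvalResult("gbm", "with_shape", np.asarray(aucs, float), [])

    def test_identical_vectors_give_p_one(self):
        a = self._res(np.linspace(0.5, 0.8, 20))
        assert compare_models(a, self._res(a.aucs.copy())).p_value == 1.0

    def test_uniform_improvement_gives_extreme_exact_tail(self):
        base = np.linspace(0.5, 0.8, 20)
        p = compare_models(self._res(base + 0.05), self._res(base)).p_value
        assert p == pytest.approx(2 * 2**-20)

    def test_varying_improvement_same_sign_pattern_same_p(self):
        rng = np.random.default_rng(2)
        base = np.linspace(0.5, 0.8, 20)
        gains = rng.uniform(0.01, 0.06, 20)
        p = compare_models(self._res(base + gains), self._res(base)).p_value
        assert p == pytest.approx(2 * 2**-20)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._res([0.5] * 20), self._res([0.5] * 19))

    def test_matches_scipy_exact_on_untied_differences(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0.4, 0.8, 20)
        other = base + rng.normal(0.01, 0.04, 20)
        ours = compare_models(self._res(other), self._res(base)).p_value
        ref = stats.wilcoxon(other - base, method="exact").pvalue
        assert ours == pytest.approx(float(ref))


class TestVariableImportance:
    def _table(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        return pd.DataFrame({
            "informative": y + rng.normal(0, 0.1, n),
            "noise": rng.normal(size=n),
            "constant": 1.0,
            "label": y})

    def test_informative_feature_outranks_noise(self):
        table = self._table()
        spec = LearnerSpec("random_forest", FAST["random_forest"], 0)
        imp = variable_importance(table, spec, seed=0, n_permutations=20)
        assert imp.method == "oob_permutation_mda"
        assert imp.ranking()[0] == "informative"
        assert imp.values["informative"] > imp.values["noise"]

    def test_constant_column_has_zero_permutation_importance(self):
        table = self._table()
        spec = LearnerSpec("cart", FAST["cart"], 0)
        imp = variable_importance(table, spec, seed=0, n_permutations=10)
        assert imp.values["constant"] == pytest.approx(0.0)

    def test_solely_linked_savr_ratio_ranks_first(self):
        """When the SA:V T1/T0 ratio is the only class-linked column in
        the table, the forest's OOB importance ranks it first."""
        rng = np.random.default_rng(42)
        n = 300
        y = (rng.random(n) < 0.3).astype(int)
        table = pd.DataFrame(
            {f"{name}_ratio": rng.normal(1.0, 0.2, n)
             for name in ("mesh_volume", "surface_area", "sphericity",
                          "elongation", "flatness")})
        table["ftv_ratio"] = rng.normal(0.6, 0.2, n)
        table["age"] = rng.normal(50, 10, n)
        # RCB-III keeps its shape: lower SA:V ratio in the positive class
        table["surface_area_to_volume_ratio_ratio"] = np.where(
            y == 1, rng.normal(1.10, 0.15, n), rng.normal(1.45, 0.18, n))
        table["label"] = y
        spec = LearnerSpec("random_forest", FAST["random_forest"], 3)
        imp = variable_importance(table, spec, seed=3)
        assert imp.method == "oob_permutation_mda"
        assert imp.ranking()[0] == "surface_area_to_volume_ratio_ratio"

    def test_elastic_net_uses_sd_scaled_coefficients(self):
        table = self._table()
        spec = LearnerSpec("elastic_net", FAST["elastic_net"], 0)
        imp = variable_importance(table, spec, seed=0)
        assert imp.method == "scaled_coefficients"
        assert imp.ranking()[0] == "informative"
        # indicator-style (one-hot) columns are excluded by contract
        table2 = table.rename(columns={"noise": "race=Other"})
        imp2 = variable_importance(table2, spec, seed=0)
        assert "race=Other" not in imp2.values.index


class TestSubgroup:
    def _cohort(self, n=160, positives=40, seed=0):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, int)
        y[:positives] = 1
        table = pd.DataFrame({
            "signal": y + rng.normal(0, 0.5, n),
            "ftv_ratio": rng.normal(size=n),
            "label": y})
        subtype = pd.Series(["TN"] * n, index=table.index)
        return table, subtype

    def test_event_starved_stratum_is_omitted(self):
        table, subtype = self._cohort(positives=4)
        notice = subgroup_eval(table, subtype, "TN",
                               ResamplingPlan(n_outer=2, seed=0),
                               [LearnerSpec("cart", FAST["cart"], 0)],
                               without_shape_columns=["ftv_ratio"])
        assert isinstance(notice, OmissionNotice)
        assert notice.n_positives == 4
        assert "omitted" in str(notice)

    def test_adequate_stratum_runs_both_feature_sets(self):
        table, subtype = self._cohort(positives=40)
        out = subgroup_eval(table, subtype, "TN",
                            ResamplingPlan(n_outer=3, seed=0),
                            [LearnerSpec("cart", FAST["cart"], 0)],
                            without_shape_columns=["ftv_ratio"])
        assert set(out) == {"with_shape", "without_shape"}
        assert len(out["with_shape"]) == 1

    def test_empty_stratum_is_an_error(self):
        table, subtype = self._cohort()
        with pytest.raises(ValueError, match="empty"):
            subgroup_eval(table, subtype, "HR+/HER2+",
                          ResamplingPlan(seed=0), [], ["ftv_ratio"])


class TestUnivariate:
    def test_fisher_2x4_matches_r_reference(self):
        """The 2x4 subtype-by-cohort margin table has exact p = 0.024,
        cross-checked against R's fisher.test."""
        table = np.array([[358, 147, 75, 330], [24, 9, 14, 33]])
        assert round(fisher_exact_rxc(table), 3) == 0.024

    def test_fisher_2x2_delegates_to_standard_implementation(self):
        t = np.array([[8, 2], [1, 5]])
        assert fisher_exact_rxc(t) == pytest.approx(
            float(stats.fisher_exact(t)[1]))

    def test_identical_groups_give_unit_p(self):
        numeric = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        rep = univariate_report(numeric, labels)
        assert rep["numeric"].loc[0, "p_value"] == 1.0

    def test_spearman_of_monotone_transform_is_one(self):
        rng = np.random.default_rng(1)
        ftv = pd.Series(rng.random(50))
        feats = pd.DataFrame({"cube": ftv**3, "neg": -ftv})
        rho = spearman_ftv_correlations(ftv, feats)
        assert rho["cube"] == pytest.approx(1.0)
        assert rho["neg"] == pytest.approx(-1.0)

    def test_categorical_report_includes_fisher_p(self):
        rng = np.random.default_rng(2)
        labels = pd.Series(rng.integers(0, 2, 60))
        cat = pd.DataFrame({"grp": rng.choice(list("ABC"), 60)})
        rep = univariate_report(pd.DataFrame({"x": rng.random(60)}),
                                labels, categorical=cat)
        p = rep["categorical"].loc[0, "p_value"]
        assert 0 < p <= 1
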