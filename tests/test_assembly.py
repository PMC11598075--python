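"""Cohort filters, endpoint dichotomization, table assembly and the
forest imputer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ftvmorph.assembly import (ENDPOINTS, ForestImputer, N_SHAPE_VARIABLES,
                               PatientRecord, apply_cohort_filters,
                               assemble_table, dichotomize, impute_missing,
                               shape_column_names)
from ftvmorph.shape import FEATURE_NAMES
from ftvmorph.synthetic import CohortConfig, draw_patient_attributes


def make_record(i, **flags):
    return PatientRecord(patient_id=f"P{i:04d}", age=50.0, race="White",
                         menopausal_status="Premenopausal",
                         hrher2_subtype="HR+/HER2-", rcb_class="RCB-II",
                         **flags)


class TestCohortFilters:
    def test_flow_arithmetic_matches_trial_flowchart(self):
        """990 eligible with 45/3/17/15 disjoint exclusions leaves 910."""
        records = []
        i = 0
        for reason, n in (("missing_pathology", 45), ("missing_clinpath", 3),
                          ("missing_mri", 17), ("poor_quality", 15)):
            for _ in range(n):
                records.append(make_record(i, **{reason: True}))
                i += 1
        while i < 990:
            records.append(make_record(i))
            i += 1
        analysis, excluded, report = apply_cohort_filters(records)
        assert report["eligible"] == 990
        assert report["analysis"] == len(analysis) == 910
        assert report["excluded_by_reason"] == {
            "missing_pathology": 45, "missing_clinpath": 3,
            "missing_mri": 17, "poor_quality": 15}

    def test_no_flags_keeps_everyone(self):
        analysis, excluded, _ = apply_cohort_filters(
            [make_record(i) for i in range(10)])
        assert len(analysis) == 10 and not excluded

    def test_double_flag_counted_once_under_first_reason(self):
        rec = make_record(0, missing_mri=True, poor_quality=True)
        _, excluded, report = apply_cohort_filters([rec])
        assert len(excluded) == 1
        assert report["excluded_by_reason"]["missing_mri"] == 1
        assert report["excluded_by_reason"]["poor_quality"] == 0


class TestDichotomize:
    @pytest.mark.parametrize("rcb, endpoint, expected", [
        ("RCB-III", "rcb3", 1), ("RCB-II", "rcb3", 0), ("RCB-0", "rcb3", 0),
        ("RCB-0", "pcr", 1), ("RCB-I", "pcr", 0),
        ("RCB-I", "rcb01", 1), ("RCB-0", "rcb01", 1), ("RCB-II", "rcb01", 0),
    ])
    def test_three_dichotomizations(self, rcb, endpoint, expected):
        assert dichotomize(rcb, endpoint) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="RCB"):
            dichotomize("unknown", "rcb3")

    def test_rcb3_prevalence_matches_margins(self):
        config = CohortConfig(n_patients=2000, seed=21)
        labels = [draw_patient_attributes(config, i)["rcb_class"]
                  for i in range(2000)]
        frac = np.mean([dichotomize(c, "rcb3") for c in labels])
        assert frac == pytest.approx(0.155, abs=0.03)


def _toy_tables(n=6, missing_t1_for=()):
    rng = np.random.default_rng(0)
    ids = [f"P{i:04d}" for i in range(n)]
    def feat_df(missing_ids=()):
        df = pd.DataFrame(rng.random((n, 17)), columns=FEATURE_NAMES)
        df.insert(0, "patient_id", ids)
        for pid in missing_ids:
            df.loc[df.patient_id == pid, list(FEATURE_NAMES)] = np.nan
        return df
    t0 = feat_df()
    t1 = feat_df(missing_t1_for)
    ratio = feat_df(missing_t1_for)
    ftv = pd.Series(rng.random(n), index=pd.Index(ids, name="patient_id"))
    cov = pd.DataFrame({"patient_id": ids, "age": 50.0,
                        "race": ["White", "Asian"] * (n // 2),
                        "menopausal_status": "Premenopausal",
                        "hrher2_subtype": ["HR+/HER2-", "HR-/HER2-"] * (n // 2)})
    labels = pd.Series(["RCB-0", "RCB-III"] * (n // 2),
                       index=pd.Index(ids, name="patient_id"))
    return t0, t1, ratio, ftv, cov, labels


class TestAssembleTable:
    def test_complete_inputs_give_51_shape_columns_no_missing(self):
        table = assemble_table(*_toy_tables(), endpoint="rcb3")
        shape_cols = [c for c in table.columns if c in shape_column_names()]
        assert len(shape_cols) == N_SHAPE_VARIABLES == 51
        assert table["label"].tolist() == [0, 1] * 3
        assert not table.isna().any().any()

    def test_degenerate_t1_propagates_to_t1_and_ratio_columns(self):
        table = assemble_table(*_toy_tables(missing_t1_for=["P0001"]))
        row = table.loc["P0001"]
        t1_cols = [f"{n}_t1" for n in FEATURE_NAMES]
        ratio_cols = [f"{n}_ratio" for n in FEATURE_NAMES]
        t0_cols = [f"{n}_t0" for n in FEATURE_NAMES]
        assert row[t1_cols].isna().all()
        assert row[ratio_cols].isna().all()
        assert row[t0_cols].notna().all()

    def test_patient_mismatch_is_an_error(self):
        t0, t1, ratio, ftv, cov, labels = _toy_tables()
        with pytest.raises(ValueError, match="patient ids"):
            assemble_table(t0, t1.iloc[:-1], ratio, ftv, cov, labels)


class TestForestImputer:
    def test_complete_table_returned_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        df["label"] = rng.integers(0, 2, 20)
        out = impute_missing(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_perfect_predictor_recovers_masked_column(self):
        """B duplicates A; with 10% of B masked the forest recovers the
        masked entries to ~1% RMSE of the value range."""
        rng = np.random.default_rng(2)
        a = rng.random(300)
        df = pd.DataFrame({"a": a, "b": a.copy(),
                           "c": rng.random(300)})
        mask_idx = rng.choice(300, 30, replace=False)
        truth = df.loc[mask_idx, "b"].copy()
        df.loc[mask_idx, "b"] = np.nan
        imp = ForestImputer(n_estimators=100, seed=0)
        out = imp.fit_transform(df)
        rmse = float(np.sqrt(((out.loc[mask_idx, "b"] - truth) ** 2).mean()))
        assert rmse < 0.01
        # observed entries untouched
        obs = df.index.difference(mask_idx)
        assert np.array_equal(out.loc[obs, "b"], df.loc[obs, "b"])

    def test_imputed_values_stay_inside_observed_range(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 2, (100, 3)), columns=list("xyz"))
        df.loc[rng.choice(100, 15, replace=False), "y"] = np.nan
        observed = df["y"].dropna()
        out = ForestImputer(n_estimators=50, seed=0).fit_transform(df)
        assert out["y"].min() >= observed.min() - 1e-9
        assert out["y"].max() <= observed.max() + 1e-9

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            ForestImputer().fit_transform(df)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        df.loc[rng.choice(60, 10, replace=False), "c"] = np.nan
        out1 = ForestImputer(n_estimators=20, seed=7).fit_transform(df)
        out2 = ForestImputer(n_estimators=20, seed=7).fit_transform(df)
        pd.testing.assert_frame_equal(out1, out2)

    def test_forest_beats_mean_fill_on_correlated_features(self):
        """On MAR-masked tables with a latent factor, forest imputation
        RMSE is below mean-imputation RMSE (paired over 20 replicates)."""
        diffs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            z = rng.normal(size=80)
            df = pd.DataFrame({
                f"f{j}": z + rng.normal(scale=0.3, size=80) for j in range(4)})
            # masking depends on an observed column: missing at random
            at_risk = np.argsort(df["f0"].to_numpy())[40:]
            mask_idx = rng.choice(at_risk, 12, replace=False)
            truth = df.loc[mask_idx, "f3"].copy()
            masked = df.copy()
            masked.loc[mask_idx, "f3"] = np.nan
            out = ForestImputer(n_estimators=30, seed=rep).fit_transform(masked)
            rmse_rf = np.sqrt(((out.loc[mask_idx, "f3"] - truth) ** 2).mean())
            rmse_mean = np.sqrt(((masked["f3"].mean() - truth) ** 2).mean())
            diffs.append(rmse_mean - rmse_rf)
        assert stats.wilcoxon(diffs, alternative="greater").pvalue < 0.05

    def test_transform_fills_new_rows_without_refitting(self):
        rng = np.random.default_rng(5)
        a = rng.random(200)
        train = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.05, 200)})
        train.loc[rng.choice(200, 20, replace=False), "b"] = np.nan
        imp = ForestImputer(n_estimators=50, seed=1)
        imp.fit_transform(train)
        a_new = rng.random(30)
        test = pd.DataFrame({"a": a_new, "b": np.nan})
        out = imp.transform(test)
        assert out["b"].notna().all()
        assert np.corrcoef(out["b"], a_new)[0, 1] > 0.9
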