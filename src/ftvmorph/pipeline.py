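"""End-to-end pipeline: simulate (or ingest) -> FTV -> mask conditioning
-> shape features -> table assembly and imputation -> nested-resampling
evaluation with and without shape features -> reports.

Every stage is the corresponding library call; this module only wires
them together, tracks provenance, and serializes results. The whole run
is reproducible from (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import (LABEL_COLUMN, assemble_table, impute_missing,
                       shape_column_names)
from .config import PipelineConfig
from .core import DceExam, TumorMask
from .enhancement import UndefinedRatioError, exam_ftv, ftv_ratio
from .evaluate import (FAMILIES, EvalResult, LearnerSpec, ResamplingPlan,
                       compare_models, default_grid, nested_cv, select_optimal,
                       variable_importance)
from .morphology import preprocess
from .shape import (FEATURE_NAMES, ShapeFeatureVector, compute_shape_features,
                    shape_ratios)
from .synthetic import CohortBundle, CohortConfig, simulate_cohort


class PipelineError(RuntimeError):
    """Stage failure, annotated with stage name and patient id."""

    def __init__(self, stage: str, patient_id: str, message: str):
        super().__init__(f"[stage={stage}] [patient={patient_id}] {message}")
        self.stage = stage
        self.patient_id = patient_id


def exam_shape_features(exam: DceExam, cfg: PipelineConfig
                        ) -> Tuple[float, ShapeFeatureVector, Dict[str, int]]:
    """FTV (mm^3), shape feature vector and conditioning log for one exam."""
    ftv = exam_ftv(exam, pe_min=cfg.pe_min, ser_min=cfg.ser_min,
                   ser_max=cfg.ser_max)
    cleaned, log = preprocess(ftv.mask, target_spacing=cfg.target_spacing,
                              close_radius=cfg.close_radius,
                              aa_iterations=cfg.aa_iterations,
                              aa_max_rms=cfg.aa_max_rms,
                              min_size=cfg.min_size,
                              connectivity=cfg.connectivity)
    return ftv.ftv_mm3, compute_shape_features(cleaned), log


def cohort_feature_table(bundle: CohortBundle, cfg: PipelineConfig
                         ) -> Tuple[pd.DataFrame, dict]:
    """Run imaging stages for every patient and assemble the table.

    Returns the modelling table (51 shape variables + ftv_ratio +
    encoded covariates + outcome) plus an auxiliary dict with raw
    covariates, FTV values and the per-patient flow log.
    """
    rows_t0, rows_t1, rows_ratio = [], [], []
    ftv_vals, flow = [], []
    for (e0, e1) in bundle.exams:
        pid = e0.patient_id
        try:
            ftv0, f0, log0 = exam_shape_features(e0, cfg)
            ftv1, f1, log1 = exam_shape_features(e1, cfg)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError("shape_features", pid, str(exc)) from exc
        try:
            fr = ftv_ratio(ftv0, ftv1)
        except UndefinedRatioError:
            fr = np.nan  # missing, routed to imputation
        rows_t0.append({"patient_id": pid, **f0.to_dict()})
        rows_t1.append({"patient_id": pid, **f1.to_dict()})
        rows_ratio.append({"patient_id": pid, **shape_ratios(f0, f1)})
        ftv_vals.append({"patient_id": pid, "ftv_t0_mm3": ftv0,
                         "ftv_t1_mm3": ftv1, "ftv_ratio": fr,
                         "t0_missing": f0.missing, "t1_missing": f1.missing})
        flow.append({"patient_id": pid, "t0_log": log0, "t1_log": log1,
                     "degenerate_t1": f1.missing})
    ftv_df = pd.DataFrame(ftv_vals).set_index("patient_id")
    if ftv_df["ftv_ratio"].isna().all():
        raise PipelineError("assembly", "-",
                            "all FTV ratios are missing (no tumor segmented "
                            "at T0 anywhere; check thresholds)")
    covariates = bundle.covariates.set_index("patient_id")
    labels = bundle.labels.set_index("patient_id")["rcb_class"]
    table = assemble_table(pd.DataFrame(rows_t0), pd.DataFrame(rows_t1),
                           pd.DataFrame(rows_ratio), ftv_df["ftv_ratio"],
                           covariates.reset_index(), labels,
                           endpoint=cfg.endpoint)
    aux = {"covariates": covariates, "labels": labels, "ftv": ftv_df,
           "flow": flow}
    return table, aux


def without_shape_columns(table: pd.DataFrame) -> List[str]:
    """FTV ratio plus clinicopathologic covariates (no shape variables)."""
    shape_cols = set(shape_column_names())
    return [c for c in table.columns
            if c not in shape_cols and c != LABEL_COLUMN]


def evaluate_table(table: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Four learners, with and without shape features, plus comparison
    of the optimal models and the importance ranking of the optimal
    with-shape model."""
    plan = ResamplingPlan(n_outer=cfg.n_outer, test_fraction=cfg.test_fraction,
                          inner_folds=cfg.inner_folds, seed=cfg.seed)
    if cfg.imputation == "whole_table" and table.isna().any().any():
        table = impute_missing(table, seed=cfg.seed,
                               n_estimators=cfg.imputer_trees)
    wo_cols = without_shape_columns(table)
    results: Dict[str, List[EvalResult]] = {"with_shape": [], "without_shape": []}
    for family in FAMILIES:
        learner = LearnerSpec(family=family,
                              grid=tuple(default_grid(family, cfg.grid_preset)),
                              seed=cfg.seed)
        results["with_shape"].append(
            nested_cv(table, learner, plan, feature_set="with_shape",
                      imputer_trees=cfg.imputer_trees))
        results["without_shape"].append(
            nested_cv(table, learner, plan, feature_columns=wo_cols,
                      feature_set="without_shape",
                      imputer_trees=cfg.imputer_trees))
    best_with = select_optimal(results["with_shape"])
    best_without = select_optimal(results["without_shape"])
    comparison = compare_models(best_with, best_without)
    imp_table = table if not table.isna().any().any() else impute_missing(
        table, seed=cfg.seed, n_estimators=cfg.imputer_trees)
    importance = variable_importance(
        imp_table, LearnerSpec(family=best_with.family,
                               grid=tuple(default_grid(best_with.family,
                                                       cfg.grid_preset)),
                               seed=cfg.seed),
        seed=cfg.seed, n_permutations=cfg.importance_permutations)
    return {"results": results, "optimal_with": best_with,
            "optimal_without": best_without, "comparison": comparison,
            "importance": importance}


def _results_json(evaluation: dict, cfg: PipelineConfig) -> dict:
    return {
        "config": {"endpoint": cfg.endpoint, "n_patients": cfg.n_patients,
                   "seed": cfg.seed, "grid_preset": cfg.grid_preset},
        "learners": {fs: [r.to_dict() for r in rs]
                     for fs, rs in evaluation["results"].items()},
        "optimal": {
            "with_shape": evaluation["optimal_with"].to_dict(),
            "without_shape": evaluation["optimal_without"].to_dict()},
        "comparison": {
            "statistic": evaluation["comparison"].statistic,
            "p_value": evaluation["comparison"].p_value},
        "importance": {
            "method": evaluation["importance"].method,
            "values": {k: float(v)
                       for k, v in evaluation["importance"].values.items()}},
    }


def run_pipeline(cfg: PipelineConfig, out_dir: Optional[str | Path] = None
                 ) -> dict:
    """Simulate a cohort under the config and run the full analysis.

    Returns a bundle with the feature table, per-learner results for
    both feature sets, the optimal-model comparison and the importance
    ranking; optionally writes results JSON/CSVs under ``out_dir``.
    Rerunning with the same config produces byte-identical output.
    """
    cohort_cfg = CohortConfig(n_patients=cfg.n_patients, seed=cfg.seed,
                              **cfg.cohort_overrides)
    bundle = simulate_cohort(cohort_cfg)
    table, aux = cohort_feature_table(bundle, cfg)
    evaluation = evaluate_table(table, cfg)
    out = {"table": table, "aux": aux, **evaluation}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "feature_table.csv")
        aux["ftv"].to_csv(out_dir / "ftv.csv")
        payload = _results_json(evaluation, cfg)
        (out_dir / "results.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        evaluation["importance"].values.rename("importance").to_csv(
            out_dir / "importance.csv")
    return out
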