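"""Modelling-table assembly: cohort filters, endpoint dichotomization,
51 shape variables + FTV ratio + covariates, and forest-based imputation.

The table has one row per patient and exactly 51 shape-derived columns
(17 features at T0, 17 at T1, 17 T1/T0 ratios), the FTV ratio, age,
one-hot-encoded categorical covariates, and a binary outcome column.
Missing values (degenerate masks, undefined ratios) are NaN and are
filled by an iterative random-forest imputer in the style of missForest:
initialize missing numerics at column medians, then repeatedly regress
each incomplete column on all others with a random forest, updating the
missing entries, until the average change between sweeps stops
decreasing or an iteration cap is hit. Observed entries are never
altered and the outcome column is never used by the imputer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .shape import FEATURE_NAMES

#: exclusion reasons, in precedence order; a doubly flagged record is
#: counted once under the earliest reason
EXCLUSION_PRECEDENCE = ("missing_pathology", "missing_clinpath",
                        "missing_mri", "poor_quality")

#: endpoint name -> set of positive RCB classes
ENDPOINTS: Dict[str, frozenset] = {
    "pcr": frozenset({"RCB-0"}),
    "rcb01": frozenset({"RCB-0", "RCB-I"}),
    "rcb3": frozenset({"RCB-III"}),
}

LABEL_COLUMN = "label"
N_SHAPE_VARIABLES = 3 * len(FEATURE_NAMES)  # 51


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    race: str
    menopausal_status: str
    hrher2_subtype: str
    rcb_class: str
    missing_pathology: bool = False
    missing_clinpath: bool = False
    missing_mri: bool = False
    poor_quality: bool = False

    def exclusion_reason(self) -> Optional[str]:
        for reason in EXCLUSION_PRECEDENCE:
            if getattr(self, reason):
                return reason
        return None


def apply_cohort_filters(records: Sequence[PatientRecord]
                         ) -> Tuple[List[PatientRecord], List[PatientRecord], dict]:
    """Split records into analysis and excluded sets with a flow report.

    The report counts each excluded patient exactly once, under the
    first flag in precedence order (pathology, then clinicopathologic
    data, then missing MRI, then MRI quality).
    """
    analysis, excluded = [], []
    counts = {reason: 0 for reason in EXCLUSION_PRECEDENCE}
    for rec in records:
        reason = rec.exclusion_reason()
        if reason is None:
            analysis.append(rec)
        else:
            excluded.append(rec)
            counts[reason] += 1
    report = {"eligible": len(records), "analysis": len(analysis),
              "excluded": len(excluded), "excluded_by_reason": counts}
    return analysis, excluded, report


def dichotomize(rcb_class: str, endpoint: str) -> int:
    """Binary outcome under one of the three RCB dichotomizations."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; use one of {sorted(ENDPOINTS)}")
    if rcb_class not in {"RCB-0", "RCB-I", "RCB-II", "RCB-III"}:
        raise ValueError(f"unknown RCB class {rcb_class!r} (should have been filtered)")
    return int(rcb_class in ENDPOINTS[endpoint])


def shape_column_names() -> List[str]:
    return ([f"{n}_t0" for n in FEATURE_NAMES]
            + [f"{n}_t1" for n in FEATURE_NAMES]
            + [f"{n}_ratio" for n in FEATURE_NAMES])


def encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode the categorical covariates, keeping age numeric.

    The largest observed category of each variable is the (dropped)
    reference level; 'Unknown' categories are retained as ordinary
    levels.
    """
    out = pd.DataFrame(index=cov.index)
    out["age"] = cov["age"].astype(float)
    for col in ("race", "menopausal_status", "hrher2_subtype"):
        counts = cov[col].value_counts()
        ref = counts.index[0]
        for level in counts.index[1:]:
            safe = str(level).replace(" ", "_").replace("/", "").replace("+", "pos") \
                             .replace("-", "neg")
            out[f"{col}={safe}"] = (cov[col] == level).astype(float)
    return out


def assemble_table(shape_t0: pd.DataFrame, shape_t1: pd.DataFrame,
                   shape_ratio: pd.DataFrame, ftv_ratio: pd.Series,
                   covariates: pd.DataFrame, labels: pd.Series,
                   endpoint: str = "rcb3") -> pd.DataFrame:
    """Join all per-patient sources into the modelling table.

    All inputs must be indexed (or indexable) by patient_id and cover
    the same patients; a patient present in one source only is an error.
    Shape columns are suffixed _t0/_t1/_ratio in the canonical feature
    order, giving exactly 51 shape-derived columns.
    """
    def _indexed(obj, name):
        if isinstance(obj, pd.DataFrame) and "patient_id" in obj.columns:
            obj = obj.set_index("patient_id")
        if obj.index.has_duplicates:
            raise ValueError(f"duplicated patient_id in {name}")
        return obj

    shape_t0 = _indexed(shape_t0, "shape_t0")[list(FEATURE_NAMES)].add_suffix("_t0")
    shape_t1 = _indexed(shape_t1, "shape_t1")[list(FEATURE_NAMES)].add_suffix("_t1")
    shape_ratio = _indexed(shape_ratio, "shape_ratio")[list(FEATURE_NAMES)
                                                       ].add_suffix("_ratio")
    covariates = _indexed(covariates, "covariates")

    ids = set(shape_t0.index)
    for name, obj in (("shape_t1", shape_t1), ("shape_ratio", shape_ratio),
                      ("ftv_ratio", ftv_ratio), ("covariates", covariates),
                      ("labels", labels)):
        diff = ids.symmetric_difference(obj.index)
        if diff:
            raise ValueError(f"patient ids mismatch in {name}: {sorted(diff)[:10]}")

    table = pd.concat([shape_t0, shape_t1, shape_ratio], axis=1)
    if table.shape[1] != N_SHAPE_VARIABLES:
        raise ValueError(
            f"expected {N_SHAPE_VARIABLES} shape columns, got {table.shape[1]}")
    table["ftv_ratio"] = ftv_ratio.astype(float)
    table = pd.concat([table, encode_covariates(covariates)], axis=1)
    table[LABEL_COLUMN] = labels.map(lambda c: dichotomize(c, endpoint)).astype(int)
    return table


class ForestImputer:
    """Iterative random-forest imputation of numeric columns.

    fit_transform() runs the missForest-style sweep on the training
    table; transform() fills a new table using the forests from the
    final training sweep (median initialization, one prediction pass),
    so imputation fitted on an outer training set can be applied to its
    test set without leakage.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 10,
                 seed: int = 0):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.seed = seed
        self.medians_: Optional[pd.Series] = None
        self.forests_: Dict[str, RandomForestRegressor] = {}
        self.columns_: Optional[List[str]] = None
        self.n_iter_: int = 0

    def _validate(self, table: pd.DataFrame) -> None:
        fully_missing = [c for c in table.columns if table[c].isna().all()]
        if fully_missing:
            raise ValueError(f"columns entirely missing: {fully_missing}")
        if not any(table[c].notna().all() for c in table.columns):
            raise ValueError("imputation needs at least one fully observed column")

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._validate(table)
        X = table.astype(float).copy()
        miss = X.isna()
        self.medians_ = X.median()
        self.columns_ = [c for c in X.columns if miss[c].any()]
        # ascending missingness: best-observed columns are imputed first
        self.columns_.sort(key=lambda c: (int(miss[c].sum()), c))
        X = X.fillna(self.medians_)
        if not self.columns_:
            self.n_iter_ = 0
            return X

        prev_delta = np.inf
        prev_X = X.copy()
        rng = np.random.default_rng(self.seed)
        for it in range(self.max_iter):
            forests: Dict[str, RandomForestRegressor] = {}
            for col in self.columns_:
                obs = ~miss[col]
                others = [c for c in X.columns if c != col]
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    random_state=int(rng.integers(0, 2**31 - 1)))
                rf.fit(X.loc[obs, others], X.loc[obs, col])
                X.loc[miss[col], col] = rf.predict(X.loc[miss[col], others])
                forests[col] = rf
            num = ((X - prev_X) ** 2).to_numpy().sum()
            den = (X.to_numpy() ** 2).sum()
            delta = num / den if den > 0 else 0.0
            self.n_iter_ = it + 1
            if delta >= prev_delta:   # stopped improving: keep previous sweep
                X = prev_X
                break
            self.forests_ = forests
            prev_delta = delta
            prev_X = X.copy()
            if delta == 0.0:
                break
        return X

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        X = table.astype(float).copy()
        miss = X.isna()
        X = X.fillna(self.medians_)
        for col in self.columns_:
            if col in X.columns and miss[col].any() and col in self.forests_:
                others = [c for c in X.columns if c != col]
                X.loc[miss[col], col] = self.forests_[col].predict(
                    X.loc[miss[col], others])
        return X


def impute_missing(table: pd.DataFrame, seed: int = 0,
                   n_estimators: int = 100, max_iter: int = 10,
                   label_column: str = LABEL_COLUMN) -> pd.DataFrame:
    """Impute the feature columns of a modelling table.

    The outcome column is set aside during imputation and re-attached
    unchanged. A table without missing values is returned as-is.
    """
    features = table.drop(columns=[label_column], errors="ignore")
    if not features.isna().any().any():
        return table.copy()
    imputer = ForestImputer(n_estimators=n_estimators, max_iter=max_iter, seed=seed)
    filled = imputer.fit_transform(features)
    out = filled.copy()
    if label_column in table.columns:
        out[label_column] = table[label_column]
    return out
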