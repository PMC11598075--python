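"""Nested-resampling evaluation of the four learners and the
accompanying statistics.

Evaluation design: the outer loop draws 20 stratified random train/test
splits (test fraction 0.25 by default); inside each training part a
grid search with stratified 5-fold cross-validation picks the
hyperparameters, the winner is refit on the whole training part and
scored on the held-out part by rank-based AUC. Performance is reported
as the mean and SD of the 20 outer test AUCs, and models are compared
by the two-sided Wilcoxon signed-rank test on the paired AUC vectors.

Learners: elastic-net logistic regression, CART, random forest, and
gradient boosting, all via scikit-learn. Variable importance is
permutation mean-decrease-in-accuracy for the tree ensembles and
standardized-coefficient magnitude for the elastic net.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .assembly import LABEL_COLUMN, ForestImputer

FAMILIES = ("elastic_net", "cart", "random_forest", "gbm")


# --------------------------------------------------------------------------
# AUC

def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2.

    Equals the probability that a random positive outscores a random
    negative. Requires both classes present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# learners and tuning grids

def default_grid(family: str, preset: str = "paper") -> List[dict]:
    """Hyperparameter grid for one learner family.

    ``preset='paper'`` is the full evaluation grid; ``preset='fast'``
    is a reduced grid for small studies and smoke runs. Grids are
    ordered simplest-first, which is also the tie-break order.
    """
    if family == "elastic_net":
        cs = np.logspace(-2, 2, 10 if preset == "paper" else 3)
        l1s = (0.1, 0.5, 0.9, 1.0) if preset == "paper" else (0.5, 1.0)
        # simplest = strongest penalty (smallest C)
        return [{"C": float(c), "l1_ratio": float(l)} for c in cs for l in l1s]
    if family == "cart":
        depths = (2, 3, 4, 6) if preset == "paper" else (2, 4)
        leaves = (5, 10, 20) if preset == "paper" else (10,)
        return [{"max_depth": d, "min_samples_leaf": m}
                for d in depths for m in leaves]
    if family == "random_forest":
        trees = 500 if preset == "paper" else 100
        mfs = ("sqrt", 0.33, 0.2) if preset == "paper" else ("sqrt", 0.33)
        leaves = (1, 5, 10) if preset == "paper" else (5,)
        return [{"n_estimators": trees, "max_features": mf, "min_samples_leaf": m}
                for m in leaves for mf in mfs]
    if family == "gbm":
        trees = (100, 300) if preset == "paper" else (100,)
        depths = (1, 2, 3) if preset == "paper" else (1, 2)
        rates = (0.01, 0.1) if preset == "paper" else (0.1,)
        return [{"n_estimators": t, "max_depth": d, "learning_rate": r}
                for t in trees for d in depths for r in rates]
    raise ValueError(f"unknown learner family {family!r}")


@dataclass(frozen=True)
class LearnerSpec:
    family: str
    grid: Tuple[dict, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not self.grid:
            object.__setattr__(self, "grid", tuple(default_grid(self.family)))

    def build(self, params: dict, seed: int):
        if self.family == "elastic_net":
            return Pipeline([
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(solver="saga", max_iter=2000,
                                           tol=1e-3, random_state=seed,
                                           **params))])
        if self.family == "cart":
            return DecisionTreeClassifier(random_state=seed, **params)
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        if self.family == "gbm":
            return GradientBoostingClassifier(random_state=seed, **params)
        raise AssertionError


@dataclass(frozen=True)
class ResamplingPlan:
    n_outer: int = 20
    test_fraction: float = 0.25
    inner_folds: int = 5
    seed: int = 0


@dataclass
class EvalResult:
    family: str
    feature_set: str
    aucs: np.ndarray
    chosen_params: List[dict]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    def to_dict(self) -> dict:
        return {"family": self.family, "feature_set": self.feature_set,
                "aucs": [float(a) for a in self.aucs],
                "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
                "chosen_params": self.chosen_params}


def _split_xy(table: pd.DataFrame, label_column: str,
              feature_columns: Optional[Sequence[str]]):
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c != label_column]
    X = table[list(feature_columns)].astype(float)
    y = table[label_column].astype(int).to_numpy()
    return X, y, list(feature_columns)


def _tune(learner: LearnerSpec, X: pd.DataFrame, y: np.ndarray,
          inner_folds: int, seed: int) -> dict:
    """Grid search by mean inner-CV AUC; ties go to the simplest model
    (earliest grid entry)."""
    if min(np.bincount(y, minlength=2)) < inner_folds:
        raise ValueError(
            f"cannot build {inner_folds} stratified folds: minority class "
            f"has {min(np.bincount(y))} members")
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_score = None, -np.inf
    for params in learner.grid:
        fold_aucs = []
        for tr, va in splits:
            est = learner.build(params, seed)
            est.fit(X.iloc[tr], y[tr])
            fold_aucs.append(auc(est.predict_proba(X.iloc[va])[:, 1], y[va]))
        score = float(np.mean(fold_aucs))
        if score > best_score + 1e-12:
            best_score, best_params = score, params
    return best_params


def nested_cv(table: pd.DataFrame, learner: LearnerSpec, plan: ResamplingPlan,
              label_column: str = LABEL_COLUMN,
              feature_columns: Optional[Sequence[str]] = None,
              feature_set: str = "with_shape",
              imputer_trees: int = 30) -> EvalResult:
    """Nested-resampling AUC estimate for one learner.

    Outer split ``i`` is seeded ``plan.seed + i``, so the whole result
    is reproducible bit-exactly. If the table contains missing values
    they are imputed inside each outer training set (forest imputer fit
    on the training part, applied to the test part) so no test
    information reaches the models.
    """
    X, y, feature_columns = _split_xy(table, label_column, feature_columns)
    if int(y.sum()) < 8:
        raise ValueError(f"too few positives ({int(y.sum())}) for nested evaluation")
    has_missing = bool(X.isna().any().any())
    aucs, chosen = [], []
    for i in range(plan.n_outer):
        split_seed = plan.seed + i
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=plan.test_fraction, stratify=y,
            random_state=split_seed)
        if has_missing:
            imp = ForestImputer(n_estimators=imputer_trees, seed=split_seed)
            X_tr = imp.fit_transform(X_tr)
            X_te = imp.transform(X_te)
        params = _tune(learner, X_tr, y_tr, plan.inner_folds, split_seed)
        est = learner.build(params, split_seed)
        est.fit(X_tr, y_tr)
        aucs.append(auc(est.predict_proba(X_te)[:, 1], y_te))
        chosen.append(params)
    return EvalResult(family=learner.family, feature_set=feature_set,
                      aucs=np.asarray(aucs), chosen_params=chosen)


def select_optimal(results: Sequence[EvalResult]) -> EvalResult:
    """Highest mean AUC; ties broken by lower SD, then family order."""
    if not results:
        raise ValueError("no results to select from")
    return min(results, key=lambda r: (-r.mean_auc, r.sd_auc,
                                       FAMILIES.index(r.family)))


@dataclass(frozen=True)
class ComparisonResult:
    aucs_a: np.ndarray
    aucs_b: np.ndarray
    statistic: float
    p_value: float


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p for nonzero differences.

    Midranks handle tied |d| (doubled to integers); the null
    distribution of W+ is built by subset-sum dynamic programming over
    all 2^n sign assignments, so the extreme tail is exact even when
    every |difference| is tied.
    """
    r2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)
    w_plus = int(r2[d > 0].sum())
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:len(dist) - r]
        dist = 0.5 * (dist + shifted)
    p_ge = float(dist[w_plus:].sum())
    p_le = float(dist[:w_plus + 1].sum())
    return min(1.0, 2.0 * min(p_ge, p_le))


def compare_models(a: EvalResult, b: EvalResult) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on the paired AUC vectors.

    Zero differences are dropped before ranking (the classic
    treatment); tied |differences| are mid-ranked. The exact null
    distribution is used for up to 25 nonzero pairs, the normal
    approximation beyond. All-zero differences give p = 1.
    """
    if len(a.aucs) != len(b.aucs):
        raise ValueError("paired AUC vectors differ in length")
    d = np.asarray(a.aucs) - np.asarray(b.aucs)
    nz = d[d != 0]
    if nz.size == 0:
        return ComparisonResult(a.aucs, b.aucs, 0.0, 1.0)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if nz.size <= 25:
        p = _signed_rank_exact_p(nz)
    else:
        p = float(stats.wilcoxon(nz, alternative="two-sided",
                                 method="approx").pvalue)
    return ComparisonResult(a.aucs, b.aucs, w_plus, p)


# --------------------------------------------------------------------------
# variable importance

@dataclass
class ImportanceTable:
    method: str
    values: pd.Series  # variable -> importance, descending

    def ranking(self) -> List[str]:
        return list(self.values.index)


def fit_tuned(table: pd.DataFrame, learner: LearnerSpec, seed: int,
              label_column: str = LABEL_COLUMN,
              inner_folds: int = 5):
    """Tune on the full table by inner CV and refit the winner."""
    X, y, cols = _split_xy(table, label_column, None)
    params = _tune(learner, X, y, inner_folds, seed)
    est = learner.build(params, seed)
    est.fit(X, y)
    return est, params, X, y


def _rf_oob_mda(model, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Per-tree out-of-bag permutation mean decrease in accuracy (%).

    The classic forest importance: for every tree, classification
    accuracy on its out-of-bag rows is compared before and after
    permuting one variable, and the decrease is averaged over trees.
    Measuring per tree on held-out rows avoids both the memorization of
    an in-sample measurement and the masking of correlated variables by
    ensemble redundancy.
    """
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)
    n = len(y)
    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    rng = np.random.default_rng(seed)
    imp = np.zeros(X.shape[1])
    for tree in model.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = (tree.predict(X_oob) == y_oob).mean()
        for j in range(X.shape[1]):
            X_perm = X_oob.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            imp[j] += base - (tree.predict(X_perm) == y_oob).mean()
    return 100.0 * imp / len(model.estimators_)


def variable_importance(table: pd.DataFrame, learner: LearnerSpec,
                        seed: int = 0, n_permutations: int = 50,
                        label_column: str = LABEL_COLUMN) -> ImportanceTable:
    """Importance ranking of all model variables.

    Random forest: per-tree out-of-bag permutation importance, the mean
    decrease in accuracy (%). CART/GBM: ensemble-level permutation
    importance at the 0.5 score threshold over ``n_permutations``
    seeded shuffles of each column. Elastic net: magnitude of the
    standardized coefficient (raw coefficient times the variable's SD),
    numeric (non-indicator) variables only.
    """
    est, params, X, y = fit_tuned(table, learner, seed, label_column)
    if learner.family == "elastic_net":
        coefs = est.named_steps["clf"].coef_.ravel()
        # the scaler standardizes inputs, so these are coef * SD already
        numeric = [i for i, c in enumerate(X.columns) if "=" not in c]
        vals = pd.Series({X.columns[i]: abs(coefs[i]) for i in numeric})
        method = "scaled_coefficients"
    elif learner.family == "random_forest":
        vals = pd.Series(_rf_oob_mda(est, X.to_numpy(), y, seed),
                         index=X.columns)
        method = "oob_permutation_mda"
    else:
        rng = np.random.default_rng(seed)
        base_acc = float(((est.predict_proba(X)[:, 1] > 0.5).astype(int) == y).mean())
        vals = {}
        for col in X.columns:
            drops = []
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[col] = rng.permutation(Xp[col].to_numpy())
                acc = float(((est.predict_proba(Xp)[:, 1] > 0.5).astype(int)
                             == y).mean())
                drops.append(base_acc - acc)
            vals[col] = 100.0 * float(np.mean(drops))
        vals = pd.Series(vals)
        method = "permutation_mda"
    return ImportanceTable(method=method,
                           values=vals.sort_values(ascending=False))


# --------------------------------------------------------------------------
# subgroup analysis

@dataclass(frozen=True)
class OmissionNotice:
    subtype: str
    n_patients: int
    n_positives: int
    min_events: int

    def __str__(self) -> str:
        return (f"subgroup {self.subtype!r} omitted: {self.n_positives} events "
                f"in {self.n_patients} patients (minimum {self.min_events})")


def subgroup_eval(table: pd.DataFrame, subtype: pd.Series, subtype_value: str,
                  plan: ResamplingPlan, learners: Sequence[LearnerSpec],
                  without_shape_columns: Sequence[str],
                  label_column: str = LABEL_COLUMN,
                  min_events: int = 8):
    """With/without-shape evaluation restricted to one HR/HER2 stratum.

    When the stratum has fewer than ``min_events`` positives the
    analysis is not attempted and an OmissionNotice is returned, the
    guard used for event-starved subtypes.
    """
    idx = subtype[subtype == subtype_value].index
    if len(idx) == 0:
        raise ValueError(f"empty stratum {subtype_value!r}")
    sub = table.loc[idx]
    n_pos = int(sub[label_column].sum())
    if n_pos < min_events:
        return OmissionNotice(subtype=subtype_value, n_patients=len(sub),
                              n_positives=n_pos, min_events=min_events)
    out = {"with_shape": [], "without_shape": []}
    for learner in learners:
        out["with_shape"].append(nested_cv(sub, learner, plan,
                                           label_column=label_column,
                                           feature_set="with_shape"))
        out["without_shape"].append(nested_cv(
            sub, learner, plan, label_column=label_column,
            feature_columns=list(without_shape_columns),
            feature_set="without_shape"))
    return out


# --------------------------------------------------------------------------
# univariate statistics

def fisher_exact_rxc(table: np.ndarray, seed: int = 0,
                     n_mc: int = 200_000, max_enumeration: int = 2_000_000
                     ) -> float:
    """Fisher's exact test for a 2 x c contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed one (the
    two-sided convention, with a small relative tolerance). Falls back
    to seeded Monte Carlo when the enumeration would be too large.
    Delegates to the standard 2x2 implementation when c = 2.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t)[1])
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    n = int(t.sum())
    # work with the smaller row for a smaller enumeration
    r = int(row.argmin())
    a_obs = t[r]
    m = int(row[r])

    def log_p(a: np.ndarray) -> np.ndarray:
        # log P(a) = sum_j log C(col_j, a_j) - log C(n, m)
        from scipy.special import gammaln
        lc = (gammaln(col + 1) - gammaln(a + 1) - gammaln(col - a + 1))
        return lc.sum(axis=-1) - (gammaln(n + 1) - gammaln(m + 1)
                                  - gammaln(n - m + 1))

    ranges = [np.arange(min(c, m) + 1) for c in col[:-1]]
    n_combo = int(np.prod([len(r_) for r_ in ranges]))
    if n_combo <= max_enumeration:
        grids = np.meshgrid(*ranges, indexing="ij")
        free = np.stack([g.ravel() for g in grids], axis=-1)
        last = m - free.sum(axis=1)
        ok = (last >= 0) & (last <= col[-1])
        tables = np.concatenate([free[ok], last[ok, None]], axis=1)
        lp = log_p(tables)
        lp_obs = float(log_p(a_obs[None])[0])
        return float(np.exp(lp[lp <= lp_obs + 1e-7]).sum())
    # Monte Carlo: permute group labels over individuals
    rng = np.random.default_rng(seed)
    lp_obs = float(log_p(a_obs[None])[0])
    cats = np.repeat(np.arange(len(col)), col)
    hits = 1  # observed table counts as one of the samples
    draws = np.empty((n_mc, len(col)), dtype=int)
    for i in range(n_mc):
        picks = rng.choice(cats, size=m, replace=False)
        draws[i] = np.bincount(picks, minlength=len(col))
    lp_draws = log_p(draws)
    hits += int((lp_draws <= lp_obs + 1e-7).sum())
    return hits / (n_mc + 1)


def univariate_report(numeric: pd.DataFrame, labels: pd.Series,
                      categorical: Optional[pd.DataFrame] = None,
                      seed: int = 0) -> Dict[str, pd.DataFrame]:
    """Group-contrast statistics between outcome groups.

    Numeric variables: per-group median [IQR] with a two-sided
    Mann-Whitney rank-sum p-value (the groups are independent, so the
    unpaired rank test is the appropriate one; the signed-rank test is
    reserved for paired model AUCs). Categorical variables: per-level
    counts with Fisher's exact p.
    """
    y = labels.astype(int)
    rows = []
    for col in numeric.columns:
        v = numeric[col].astype(float)
        g1, g0 = v[y == 1].dropna(), v[y == 0].dropna()
        if len(g1) and len(g0):
            if np.array_equal(np.sort(g1), np.sort(g0)):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(g1, g0,
                                             alternative="two-sided").pvalue)
        else:
            p = np.nan
        rows.append({
            "variable": col,
            "median_pos": g1.median(), "iqr_lo_pos": g1.quantile(0.25),
            "iqr_hi_pos": g1.quantile(0.75),
            "median_neg": g0.median(), "iqr_lo_neg": g0.quantile(0.25),
            "iqr_hi_neg": g0.quantile(0.75), "p_value": p})
    report = {"numeric": pd.DataFrame(rows)}
    if categorical is not None:
        crows = []
        for col in categorical.columns:
            ct = pd.crosstab(y, categorical[col])
            p = fisher_exact_rxc(ct.to_numpy(), seed=seed)
            crows.append({"variable": col, "levels": list(ct.columns),
                          "counts_neg": ct.iloc[0].tolist(),
                          "counts_pos": ct.iloc[1].tolist(), "p_value": p})
        report["categorical"] = pd.DataFrame(crows)
    return report


def spearman_ftv_correlations(ftv: pd.Series, features: pd.DataFrame
                              ) -> pd.Series:
    """Spearman correlation of FTV with each shape feature."""
    return features.apply(
        lambda col: stats.spearmanr(ftv, col, nan_policy="omit").statistic)
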