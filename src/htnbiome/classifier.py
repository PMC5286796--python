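"""Random-forest disease classifier over microbiome and metabolite variables.

The workflow mirrors the standard microbiome-marker protocol: a
stratified 80/20 train/test split; variable ranking by mean decrease in
accuracy (permutation importance) on the training partition only;
repeated stratified 10-fold cross-validation (5 trials) of nested
top-m variable subsets to pick the subset size (capped at 1000); a
refit on the selected variables; and ROC/AUC on the held-out test set
with a stratified-bootstrap percentile confidence interval. A
label-permutation null of the whole pipeline is provided for
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

MAX_SELECTED = 1000


@dataclass
class ClassifierReport:
    contrast: str
    variable_set: str
    cv_error_curve: pd.Series          # subset size -> mean CV error
    importance: pd.Series              # variable -> mean decrease accuracy, ranked
    n_selected: int
    roc: pd.DataFrame                  # columns fpr, tpr
    auc: float
    auc_ci: tuple[float, float]
    test_ids: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "variable_set": self.variable_set,
            "cv_error_curve": {int(k): float(v) for k, v in self.cv_error_curve.items()},
            "importance": {k: float(v) for k, v in self.importance.items()},
            "n_selected": self.n_selected,
            "roc": self.roc.to_dict(orient="list"),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "test_ids": self.test_ids,
        }


def _forest(seed: int, n_estimators: int = 500) -> RandomForestClassifier:
    # sqrt(p) features per split, unlimited depth
    return RandomForestClassifier(n_estimators=n_estimators, max_features="sqrt",
                                  random_state=seed, n_jobs=1)


def split_train_test(X: pd.DataFrame, y: pd.Series, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified split of sample ids preserving class proportions."""
    counts = y.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each of two classes needs at least 2 samples")
    train, test = train_test_split(list(X.index), train_size=train_frac,
                                   stratify=y.values, random_state=seed)
    return list(train), list(test)


def _subset_grid(p: int, cap: int = MAX_SELECTED) -> list[int]:
    grid, m = [], 1
    while m < min(p, cap):
        grid.append(m)
        m = max(m + 1, int(round(m * 1.8)))
    grid.append(min(p, cap))
    return sorted(set(grid))


def cv_rank_and_select(X: pd.DataFrame, y: pd.Series, folds: int = 10,
                       trials: int = 5, seed: int = 0, n_estimators: int = 500,
                       grid: list[int] | None = None
                       ) -> tuple[pd.Series, pd.Series, int]:
    """Rank variables and choose a subset size by repeated CV.

    A forest on the full training features yields a mean-decrease-
    accuracy ranking; for nested top-m subsets, classification error is
    estimated by stratified k-fold CV averaged over folds and trials.
    Returns (ranked importance, error curve indexed by m, selected m =
    argmin of the curve, ties to the smaller m, capped at 1000).
    """
    rng = np.random.default_rng(seed)
    min_class = y.value_counts().min()
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} samples; using {min_class} folds",
                      UserWarning, stacklevel=2)
        folds = max(2, int(min_class))
    rf = _forest(seed, n_estimators).fit(X.values, y.values)
    imp = permutation_importance(rf, X.values, y.values, n_repeats=5,
                                 random_state=seed, scoring="accuracy")
    importance = pd.Series(imp.importances_mean, index=X.columns)
    importance = importance.sort_values(ascending=False, kind="stable")
    order = list(importance.index)

    if grid is None:
        grid = _subset_grid(X.shape[1])
    errors = np.zeros((trials, len(grid)))
    for t in range(trials):
        t_seed = int(rng.integers(2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=t_seed)
        fold_err = np.zeros((folds, len(grid)))
        for f, (tr, te) in enumerate(skf.split(X.values, y.values)):
            for j, m in enumerate(grid):
                cols = order[:m]
                model = _forest(t_seed + f, n_estimators)
                model.fit(X.iloc[tr][cols].values, y.values[tr])
                acc = model.score(X.iloc[te][cols].values, y.values[te])
                fold_err[f, j] = 1.0 - acc
        errors[t] = fold_err.mean(axis=0)
    curve = pd.Series(errors.mean(axis=0), index=grid, name="cv_error")
    n_selected = int(curve.index[int(np.argmin(curve.values))])
    return importance, curve, min(n_selected, MAX_SELECTED)


def fit_and_roc(X: pd.DataFrame, y: pd.Series, train: list[str], test: list[str],
                selected: list[str], seed: int = 0, n_estimators: int = 500,
                n_boot: int = 2000, contrast: str = "", variable_set: str = "",
                importance: pd.Series | None = None,
                cv_error_curve: pd.Series | None = None) -> ClassifierReport:
    """Refit on the selected variables and evaluate ROC/AUC on the test set.

    The AUC confidence interval is a stratified bootstrap of the test
    scores (percentile, 2000 reps by default).
    """
    y_test = y.loc[test]
    if y_test.nunique() < 2:
        raise ValueError("test set contains a single class; AUC undefined")
    rf = _forest(seed, n_estimators)
    rf.fit(X.loc[train, selected].values, y.loc[train].values)
    pos = rf.classes_[1]
    scores = rf.predict_proba(X.loc[test, selected].values)[:, 1]
    y_bin = (y_test.values == pos).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, scores)
    auc = float(roc_auc_score(y_bin, scores))
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y_bin == 1)
    neg_idx = np.flatnonzero(y_bin == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos_idx, len(pos_idx)),
                              rng.choice(neg_idx, len(neg_idx))])
        boots[b] = roc_auc_score(y_bin[idx], scores[idx])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ClassifierReport(
        contrast=contrast, variable_set=variable_set,
        cv_error_curve=cv_error_curve if cv_error_curve is not None else pd.Series(dtype=float),
        importance=importance if importance is not None else pd.Series(dtype=float),
        n_selected=len(selected), roc=roc, auc=auc, auc_ci=ci, test_ids=list(test))


def classify(X: pd.DataFrame, y: pd.Series, seed: int = 0, folds: int = 10,
             trials: int = 5, n_estimators: int = 500, n_boot: int = 2000,
             grid: list[int] | None = None, contrast: str = "",
             variable_set: str = "") -> ClassifierReport:
    """Full pipeline: split, rank+select on the training partition, refit, ROC."""
    train, test = split_train_test(X, y, seed=seed)
    importance, curve, m = cv_rank_and_select(
        X.loc[train], y.loc[train], folds=folds, trials=trials, seed=seed,
        n_estimators=n_estimators, grid=grid)
    selected = list(importance.index[:m])
    return fit_and_roc(X, y, train, test, selected, seed=seed,
                       n_estimators=n_estimators, n_boot=n_boot, contrast=contrast,
                       variable_set=variable_set, importance=importance,
                       cv_error_curve=curve)


def permutation_null(X: pd.DataFrame, y: pd.Series, reps: int = 20, seed: int = 0,
                     folds: int = 5, trials: int = 1, n_estimators: int = 100,
                     grid: list[int] | None = None, n_boot: int = 50) -> np.ndarray:
    """Null AUC distribution: permute labels, rerun the full pipeline."""
    if reps < 20:
        raise ValueError("need at least 20 permutation replicates")
    rng = np.random.default_rng(seed)
    if grid is None:
        p = X.shape[1]
        grid = sorted({max(1, p // 8), max(2, p // 3), p})
    aucs = np.empty(reps)
    for r in range(reps):
        y_perm = pd.Series(rng.permutation(y.values), index=y.index)
        rep = classify(X, y_perm, seed=int(rng.integers(2 ** 31)), folds=folds,
                       trials=trials, n_estimators=n_estimators, grid=grid,
                       n_boot=n_boot)
        aucs[r] = rep.auc
    return aucs
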