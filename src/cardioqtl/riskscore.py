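"""Multilocus genetic risk scoring: L1-penalized logistic regression with
nested cross-validation and the 1-SE lambda rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["auc", "RiskModel", "fit_risk_model"]


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) formulation with
    midrank tie handling: U / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class RiskModel:
    """Nested-CV evaluation of one candidate feature set."""

    name: str
    fold_aucs: list
    fold_lambdas: list
    selected_features: list  # per fold: feature names with nonzero weight
    seed: int | None = None

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_aucs))


def _lambda_grid(n_lambdas: int = 30) -> np.ndarray:
    # descending lambda (ascending C); lambda = 1 / (C * n) up to scaling
    return np.logspace(1, -3, n_lambdas)


def _fit_lasso(X, y, lam):
    # random_state pins liblinear's internal shuffling -> reproducible fits
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=1.0 / (lam * len(y)), max_iter=2000,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def fit_risk_model(
    features: pd.DataFrame,
    labels,
    candidate_sets: dict,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int | None = None,
    lambdas=None,
) -> dict:
    """Evaluate candidate feature sets by nested cross-validation.

    Outer folds hold out test samples; within each training split an inner
    stratified CV scores a descending lambda path by mean AUC, and the largest
    lambda whose mean AUC is within one standard error of the maximum is
    selected (parsimony).  The model is refit on the full training split at
    that lambda and scored on the held-out fold.

    Parameters
    ----------
    features
        Sample x feature matrix (standardize SNP dosages upstream).
    candidate_sets
        Mapping name -> list of feature column names.
    Returns
    -------
    dict name -> :class:`RiskModel`.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < 20:
        raise ValueError("need at least 20 samples per class")
    if lambdas is None:
        lambdas = _lambda_grid()
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    results = {}
    for name, cols in candidate_sets.items():
        if len(cols) == 0:
            raise ValueError(f"candidate set {name!r} is empty")
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise KeyError(f"candidate set {name!r} references unknown features: {missing}")
        X = features[list(cols)].to_numpy(dtype=float)
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        fold_aucs, fold_lams, fold_feats = [], [], []
        for train_idx, test_idx in outer.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            lam = _select_lambda_1se(Xtr, ytr, lambdas, inner_folds, seed)
            clf = _fit_lasso(Xtr, ytr, lam)
            test_scores = clf.decision_function(X[test_idx])
            try:
                fold_aucs.append(auc(test_scores, y[test_idx]))
            except ValueError:  # pragma: no cover - stratification prevents this
                fold_aucs.append(float("nan"))
            fold_lams.append(lam)
            nz = np.flatnonzero(np.abs(clf.coef_[0]) > 0)
            fold_feats.append([cols[j] for j in nz])
        results[name] = RiskModel(
            name=name,
            fold_aucs=fold_aucs,
            fold_lambdas=fold_lams,
            selected_features=fold_feats,
            seed=seed,
        )
    return results


def _select_lambda_1se(X, y, lambdas, inner_folds, seed):
    """Largest lambda with inner-CV mean AUC within one SE of the maximum."""
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))
    aucs = np.zeros((len(lambdas), len(splits)))
    for k, (tr, te) in enumerate(splits):
        for i, lam in enumerate(lambdas):
            clf = _fit_lasso(X[tr], y[tr], lam)
            scores = clf.decision_function(X[te])
            try:
                aucs[i, k] = auc(scores, y[te])
            except ValueError:  # degenerate tiny fold
                aucs[i, k] = 0.5
    mean_auc = aucs.mean(axis=1)
    se_auc = aucs.std(axis=1, ddof=1) / np.sqrt(aucs.shape[1])
    best = int(np.argmax(mean_auc))
    threshold = mean_auc[best] - se_auc[best]
    # lambdas are descending: first qualifying index is the largest lambda
    for i, m in enumerate(mean_auc):
        if m >= threshold:
            return float(lambdas[i])
    return float(lambdas[best])  # pragma: no cover
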