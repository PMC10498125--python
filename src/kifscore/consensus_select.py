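"""Consensus hub-gene selection: LASSO-logistic, random forest, and SVM-RFE
over a candidate panel, intersected.

All three learners consume the same per-gene standardized matrix.  The
penalty for the LASSO is chosen at the cross-validated deviance minimum over
a log-spaced path (a one-standard-error alternative is available); the
random forest turns its impurity importances into a list via an above-mean
threshold (a declared convention — rankings alone cannot be intersected);
SVM-RFE drops the smallest-|weight| gene per round and keeps the surviving
set at the minimum of the cross-validated error curve, preferring the
smaller set on ties.  Everything is deterministic under the given seed, and
the fold assignments and seeds used are recorded in the result.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "SelectionResult",
    "standardize",
    "lasso_select",
    "rf_rank",
    "svm_rfe",
    "consensus",
    "select_hub_genes",
]


@dataclasses.dataclass
class SelectionResult:
    lasso_genes: list[str]
    rf_genes: list[str]
    rf_importances: pd.Series
    svmrfe_genes: list[str]
    svmrfe_error_curve: pd.Series  # index: surviving-set size, value: CV error
    consensus_genes: list[str]
    seed: int
    k_folds: int


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Per-gene zero-mean unit-variance scaling; constant genes are dropped
    with a warning (they carry no class information)."""
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        import logging

        logging.getLogger("kifscore").warning(
            "dropping constant gene column(s): %s", list(X.columns[~keep])
        )
    X = X.loc[:, keep]
    return (X - X.mean(axis=0)) / sd[keep]


def _check_classes(y: pd.Series | np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y


def lasso_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    Cs: np.ndarray | None = None,
    one_se: bool = False,
) -> list[str]:
    """Genes with nonzero coefficients at the CV-chosen L1 penalty.

    The path is 50 log-spaced inverse-penalties; CV picks the deviance
    (log-loss) minimum, or the sparsest model within one standard error of
    it when ``one_se`` is set.
    """
    y = _check_classes(y)
    Xs = standardize(X)
    if Cs is None:
        Cs = np.logspace(-3, 2, 50)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    mean_dev = np.empty(len(Cs))
    se_dev = np.empty(len(Cs))
    for i, C in enumerate(Cs):
        model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", random_state=seed)
        scores = cross_val_score(model, Xs.to_numpy(), y, cv=cv, scoring="neg_log_loss")
        mean_dev[i] = -scores.mean()
        se_dev[i] = scores.std(ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean_dev))
    if one_se:
        limit = mean_dev[best] + se_dev[best]
        # smallest C (strongest penalty) whose deviance is within one SE
        best = int(np.flatnonzero(mean_dev <= limit)[0])
    final = LogisticRegression(l1_ratio=1.0, C=Cs[best], solver="liblinear", random_state=seed)
    final.fit(Xs.to_numpy(), y)
    coefs = final.coef_.ravel()
    return [g for g, c in zip(Xs.columns, coefs) if c != 0.0]


def rf_rank(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[pd.Series, list[str]]:
    """Impurity importances and the above-mean-importance selection."""
    y = _check_classes(y)
    Xs = standardize(X)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(Xs.to_numpy(), y)
    imp = pd.Series(rf.feature_importances_, index=Xs.columns, name="importance")
    imp = imp.sort_values(ascending=False, kind="stable")
    selected = sorted(imp.index[imp > imp.mean()])
    return imp, selected


def svm_rfe(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.Series, list[str]]:
    """Linear-SVM recursive feature elimination with a CV error curve.

    One gene (the smallest |weight|) is dropped per round; the CV
    misclassification error of the surviving set is recorded at each size.
    The selection is the surviving set at the error minimum, ties resolved
    toward the smaller set.
    """
    y = _check_classes(y)
    Xs = standardize(X)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    surviving = list(Xs.columns)
    errors: dict[int, float] = {}
    sets: dict[int, list[str]] = {}
    while surviving:
        Xsub = Xs[surviving].to_numpy()
        svc = SVC(kernel="linear", C=1.0, class_weight="balanced")
        acc = cross_val_score(svc, Xsub, y, cv=cv, scoring="accuracy")
        errors[len(surviving)] = float(1.0 - acc.mean())
        sets[len(surviving)] = list(surviving)
        if len(surviving) == 1:
            break
        svc.fit(Xsub, y)
        weights = np.abs(svc.coef_.ravel())
        surviving.pop(int(np.argmin(weights)))
    curve = pd.Series(errors, name="cv_error").sort_index()
    best_size = min(curve.index, key=lambda k: (curve[k], k))
    return curve, sorted(sets[best_size])


def consensus(*gene_lists) -> list[str]:
    """Intersection of the method selections, in lexicographic order."""
    if not gene_lists:
        return []
    common = set(gene_lists[0])
    for lst in gene_lists[1:]:
        common &= set(lst)
    return sorted(common)


def select_hub_genes(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    one_se: bool = False,
) -> SelectionResult:
    """Run all three selectors on one standardized panel and intersect."""
    lasso_genes = lasso_select(X, y, k_folds=k_folds, seed=seed, one_se=one_se)
    rf_importances, rf_genes = rf_rank(X, y, n_trees=n_trees, seed=seed)
    error_curve, svm_genes = svm_rfe(X, y, k_folds=k_folds, seed=seed)
    return SelectionResult(
        lasso_genes=sorted(lasso_genes),
        rf_genes=rf_genes,
        rf_importances=rf_importances,
        svmrfe_genes=svm_genes,
        svmrfe_error_curve=error_curve,
        consensus_genes=consensus(lasso_genes, rf_genes, svm_genes),
        seed=seed,
        k_folds=k_folds,
    )
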