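"""Balanced-subsampling classification harness over module scores.

Class imbalance is handled by constructing folds that each contain every
minority-class sample plus an equal-size majority subsample drawn without
replacement (so folds differ only in their majority draw), split 70/30
into train/validation with class stratification.  Nine standard classifier
families are evaluated behind a fit/predict/score contract; the confusion-
matrix metrics (sensitivity, specificity, accuracy, F1, Cohen's kappa),
ROC/PR curves and permutation feature importance are computed in-repo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .scoring import ModuleScoreMatrix

__all__ = [
    "FeatureMatrix",
    "Fold",
    "FoldPlan",
    "CLASSIFIER_FAMILIES",
    "build_features",
    "make_folds",
    "confusion_metrics",
    "evaluate",
    "permutation_importance",
    "roc_pr",
]


@dataclass
class FeatureMatrix:
    """Samples x features with binary labels and dataset provenance."""

    X: pd.DataFrame
    y: pd.Series  # binary labels, aligned to X.index
    provenance: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("label index does not match feature index")
        classes = sorted(self.y.unique())
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        self.classes = classes


@dataclass(frozen=True)
class Fold:
    train: np.ndarray  # sample ids
    validation: np.ndarray


@dataclass
class FoldPlan:
    folds: list[Fold]
    n_folds: int
    seed: int
    minority_class: object
    majority_class: object
    fold_size: int


def build_features(
    score_matrices: list[ModuleScoreMatrix],
    labels: "pd.Series | dict",
) -> FeatureMatrix:
    """Concatenate module-score matrices sample-wise into a feature table.

    Matrices are aligned on their shared module vocabulary (modules missing
    from any matrix are dropped with a warning); features with missing
    values or zero inter-quartile range across all samples are removed.
    """
    if not score_matrices:
        raise ValueError("no score matrices given")
    shared = set(score_matrices[0].modules)
    for m in score_matrices[1:]:
        shared &= set(m.modules)
    dropped = set().union(*(m.modules for m in score_matrices)) - shared
    if dropped:
        warnings.warn(f"dropping modules absent from some datasets: {sorted(dropped)}")
    if not shared:
        raise ValueError("no shared modules across datasets")
    modules = sorted(shared)
    blocks, prov = [], []
    for m in score_matrices:
        blocks.append(m.scores.loc[modules].T)
        prov.extend([m.provenance] * len(m.samples))
    X = pd.concat(blocks, axis=0)
    provenance = pd.Series(prov, index=X.index)
    labels = pd.Series(labels)
    missing = [s for s in X.index if s not in labels.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    y = labels.loc[X.index]
    X = X.dropna(axis=1, how="any")
    q3 = X.quantile(0.75)
    q1 = X.quantile(0.25)
    X = X.loc[:, (q3 - q1) > 0]
    if X.shape[1] == 0:
        raise ValueError("no features survive the IQR filter")
    return FeatureMatrix(X=X, y=y, provenance=provenance)


def make_folds(
    labels: pd.Series,
    n_folds: int,
    seed: int = 0,
    split: float = 0.7,
) -> FoldPlan:
    """Balanced subsampling folds with a stratified train/validation split.

    Each fold holds every minority sample plus a without-replacement
    majority subsample of equal size; within the fold each class is split
    ``split``/(1 - split) into train/validation.
    """
    labels = pd.Series(labels)
    classes = labels.value_counts()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes.index)}")
    minority, majority = classes.index[-1], classes.index[0]
    if classes[minority] > classes[majority]:
        warnings.warn("minority class larger than majority; swapping roles")
        minority, majority = majority, minority
    minority_ids = np.array(sorted(labels.index[labels == minority]))
    majority_ids = np.array(sorted(labels.index[labels == majority]))
    m = len(minority_ids)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        maj_draw = rng.choice(majority_ids, size=m, replace=False)
        train_parts, val_parts = [], []
        for ids in (minority_ids, maj_draw):
            perm = rng.permutation(ids)
            n_train = int(round(split * len(ids)))
            train_parts.append(perm[:n_train])
            val_parts.append(perm[n_train:])
        folds.append(
            Fold(
                train=np.concatenate(train_parts),
                validation=np.concatenate(val_parts),
            )
        )
    return FoldPlan(
        folds=folds, n_folds=n_folds, seed=seed,
        minority_class=minority, majority_class=majority, fold_size=2 * m,
    )


# ---------------------------------------------------------------------------
# Classifier families (pluggable fit/predict/score contract)


def CLASSIFIER_FAMILIES(seed: int = 0) -> dict[str, object]:
    """The nine standard families at fixed, widely used defaults."""
    return {
        "LR": LogisticRegression(max_iter=2000),
        "KNN": KNeighborsClassifier(),
        "NB": GaussianNB(),
        "SVM": SVC(kernel="rbf", gamma="scale", random_state=seed),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "GB": GradientBoostingClassifier(random_state=seed),
        "DTREE": DecisionTreeClassifier(random_state=seed),
        "LDA": LinearDiscriminantAnalysis(),
        "ADB": AdaBoostClassifier(random_state=seed),
    }


def _continuous_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    return np.asarray(proba[:, 1], dtype=float)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, F1 and Cohen's kappa from counts."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (accuracy - p_e) / (1 - p_e) if p_e < 1 else 0.0
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "f1": f1,
        "kappa": kappa,
    }


@dataclass
class ClassifierReport:
    per_fold: pd.DataFrame
    aggregate: pd.DataFrame
    curves: dict[str, dict[str, object]]
    positive_class: object


def evaluate(
    features: FeatureMatrix,
    plan: FoldPlan,
    families: "list[str] | dict[str, object] | None" = None,
) -> ClassifierReport:
    """Train/evaluate each family on each fold; aggregate metrics and curves.

    The positive class is the minority class of the fold plan.  Folds whose
    validation split is single-class are skipped with a warning and
    reported as such.  ROC/PR curves are computed from validation scores
    pooled over folds.
    """
    registry = CLASSIFIER_FAMILIES(plan.seed)
    if families is None:
        models = registry
    elif isinstance(families, dict):
        models = families
    else:
        unknown = [f for f in families if f not in registry]
        if unknown:
            raise ValueError(f"unknown classifier families: {unknown}")
        models = {f: registry[f] for f in families}
    pos = plan.minority_class
    rows = []
    pooled: dict[str, dict[str, list]] = {
        name: {"scores": [], "labels": []} for name in models
    }
    from sklearn.base import clone

    for fold_i, fold in enumerate(plan.folds):
        X_tr = features.X.loc[fold.train].to_numpy(dtype=float)
        y_tr = (features.y.loc[fold.train] == pos).to_numpy(dtype=int)
        X_va = features.X.loc[fold.validation].to_numpy(dtype=float)
        y_va = (features.y.loc[fold.validation] == pos).to_numpy(dtype=int)
        if len(np.unique(y_va)) < 2 or len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {fold_i}: degenerate single-class split; skipped")
            rows.append({"fold": fold_i, "family": None, "skipped": True})
            continue
        for name, proto in models.items():
            model = clone(proto)
            model.fit(X_tr, y_tr)
            pred = np.asarray(model.predict(X_va), dtype=int)
            tp = int(((pred == 1) & (y_va == 1)).sum())
            tn = int(((pred == 0) & (y_va == 0)).sum())
            fp = int(((pred == 1) & (y_va == 0)).sum())
            fn = int(((pred == 0) & (y_va == 1)).sum())
            metrics = confusion_metrics(tp, tn, fp, fn)
            rows.append({"fold": fold_i, "family": name, "skipped": False, **metrics})
            pooled[name]["scores"].append(_continuous_scores(model, X_va))
            pooled[name]["labels"].append(y_va)
    per_fold = pd.DataFrame(rows)
    ok = per_fold[~per_fold["skipped"].astype(bool)]
    aggregate = (
        ok.groupby("family")[["sensitivity", "specificity", "accuracy", "f1", "kappa"]]
        .agg(["mean", "std"])
        if len(ok)
        else pd.DataFrame()
    )
    curves = {}
    for name, d in pooled.items():
        if not d["scores"]:
            continue
        scores = np.concatenate(d["scores"])
        labels = np.concatenate(d["labels"])
        curves[name] = roc_pr(scores, labels)
    return ClassifierReport(
        per_fold=per_fold, aggregate=aggregate, curves=curves, positive_class=pos
    )


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    metric: str = "accuracy",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean drop in a metric when each feature column is permuted.

    importance(j) = mean over repeats of
    (baseline metric - metric with column j shuffled); returned sorted
    descending.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    def score(xm: np.ndarray) -> float:
        pred = np.asarray(model.predict(xm), dtype=int)
        y_arr = np.asarray(y, dtype=int)
        tp = int(((pred == 1) & (y_arr == 1)).sum())
        tn = int(((pred == 0) & (y_arr == 0)).sum())
        fp = int(((pred == 1) & (y_arr == 0)).sum())
        fn = int(((pred == 0) & (y_arr == 1)).sum())
        return confusion_metrics(tp, tn, fp, fn)[metric]

    rng = np.random.default_rng(seed)
    x = X.to_numpy(dtype=float)
    baseline = score(x)
    importances = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            drops.append(baseline - score(xp))
        importances[j] = float(np.mean(drops))
    return pd.Series(importances, index=X.columns).sort_values(ascending=False)


def roc_pr(scores: np.ndarray, labels: np.ndarray) -> dict[str, object]:
    """ROC and PR curves with trapezoidal areas, thresholds at each score.

    Precision is taken as 1 when no positives are predicted (the zero-
    recall endpoint).  Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute ROC/PR")
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp_cum = np.cumsum(sorted_labels == 1)
    fp_cum = np.cumsum(sorted_labels == 0)
    # keep the last index of each distinct threshold
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    recall = np.r_[0.0, tp / n_pos]
    precision = np.r_[1.0, tp / (tp + fp)]
    aupr = float(np.trapezoid(precision, recall))
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "pr": pd.DataFrame({"recall": recall, "precision": precision}),
        "auroc": auroc,
        "aupr": aupr,
    }
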