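"""Leave-one-subject-out random-forest prediction of clinical status.

With ~36 participants and repeated visits, the honest evaluation unit
is the subject: each cross-validation fold holds out every visit of one
subject, the forest is fit on all remaining visits, and out-of-fold
predictions are pooled before computing metrics.  The classifier uses
balanced class weights to counter the uneven group sizes; regressors
target the four clinical scores.  Missing feature values are imputed
with the training fold's median so no information leaks from the held
out subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import confusion_matrix, roc_auc_score

from .io import VisitRecord, visits_to_frame

__all__ = [
    "LosoFolds",
    "ClassificationReport",
    "RegressionReport",
    "loso_folds",
    "classify_loso",
    "regress_loso",
    "DEFAULT_N_TREES",
]

DEFAULT_N_TREES = 500


@dataclass(frozen=True)
class LosoFolds:
    """One (train, test) split of visit indices per held-out subject."""

    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    subjects: tuple[str, ...]


@dataclass
class ClassificationReport:
    weighted_accuracy: float  # percent, support-weighted (= overall accuracy)
    balanced_accuracy: float  # percent, mean per-class recall
    per_class_recall: dict[str, float]  # percent
    auc: float  # macro one-vs-rest on pooled out-of-fold probabilities
    confusion: pd.DataFrame
    classes: tuple
    predictions: pd.DataFrame = field(repr=False, default=None)
    feature_importances: pd.Series = field(repr=False, default=None)


@dataclass
class RegressionReport:
    target: str
    mse: float
    mae: float
    explained_variance: float
    predictions: pd.DataFrame = field(repr=False, default=None)
    feature_importances: pd.Series = field(repr=False, default=None)


def loso_folds(visits: Sequence[VisitRecord]) -> LosoFolds:
    """Leave-one-subject-out folds over visit indices.

    Each subject's visits form exactly one test set; that subject never
    appears in the corresponding training set.
    """
    subjects = sorted({v.subject_id for v in visits})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least two subjects")
    by_subject = {s: [] for s in subjects}
    for i, v in enumerate(visits):
        by_subject[v.subject_id].append(i)
    folds = []
    for s in subjects:
        test = tuple(by_subject[s])
        train = tuple(i for i in range(len(visits)) if visits[i].subject_id != s)
        folds.append((train, test))
    return LosoFolds(folds=tuple(folds), subjects=tuple(subjects))


def _impute_train_median(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X_train = np.where(np.isnan(X_train), med, X_train)
    X_test = np.where(np.isnan(X_test), med, X_test)
    return X_train, X_test


def _feature_matrix(
    visits: Sequence[VisitRecord], feature_set: Sequence[str]
) -> np.ndarray:
    df = visits_to_frame(visits)
    missing = [f for f in feature_set if f not in df.columns]
    if missing:
        raise KeyError(f"features absent from visit records: {missing}")
    return df[list(feature_set)].to_numpy(float)


def classify_loso(
    visits: Sequence[VisitRecord],
    feature_set: Sequence[str],
    label_field: str = "group",
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> ClassificationReport:
    """LOSO random-forest classification with pooled out-of-fold metrics.

    ``label_field`` is any visit attribute usable as a class label
    (``"group"`` for HD/pHD/CTR, ``"dysarthria"`` for severity strata).
    """
    X = _feature_matrix(visits, feature_set)
    # labels keep their native dtype (group strings, dysarthria ints)
    y = np.asarray([getattr(v, label_field) for v in visits])
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("classification requires at least two classes")
    folds = loso_folds(visits)

    n = len(visits)
    proba = np.zeros((n, len(classes)))
    pred = np.empty(n, dtype=object)
    importances = np.zeros(len(feature_set))
    for train, test in folds.folds:
        tr, te = np.array(train), np.array(test)
        if len(set(y[tr])) < len(classes):
            warnings.warn(
                "a class is absent from a training fold; fold proceeds",
                stacklevel=2,
            )
        X_tr, X_te = _impute_train_median(X[tr], X[te])
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X_tr, y[tr])
        p = clf.predict_proba(X_te)
        for ci, c in enumerate(clf.classes_):
            proba[te, classes.index(c)] = p[:, ci]
        pred[te] = clf.predict(X_te)
        importances += clf.feature_importances_
    importances /= len(folds.folds)

    pred = np.asarray(pred.tolist())
    weighted_acc = 100.0 * float(np.mean(pred == y))
    recalls = {}
    for c in classes:
        mask = y == c
        recalls[str(c)] = 100.0 * float(np.mean(pred[mask] == c)) if mask.any() else np.nan
    balanced_acc = float(np.mean(list(recalls.values())))
    if len(classes) == 2:
        auc = float(roc_auc_score((y == classes[1]).astype(int), proba[:, 1]))
    else:
        auc = float(
            roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=list(classes))
        )
    cm = pd.DataFrame(
        confusion_matrix(y, pred, labels=list(classes)),
        index=list(classes),
        columns=list(classes),
    )
    preds_df = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in visits],
            "visit_id": [v.visit_id for v in visits],
            "true": y,
            "predicted": pred,
            **{f"p_{c}": proba[:, i] for i, c in enumerate(classes)},
        }
    )
    return ClassificationReport(
        weighted_accuracy=weighted_acc,
        balanced_accuracy=balanced_acc,
        per_class_recall=recalls,
        auc=auc,
        confusion=cm,
        classes=classes,
        predictions=preds_df,
        feature_importances=pd.Series(importances, index=list(feature_set)),
    )


def regress_loso(
    visits: Sequence[VisitRecord],
    feature_set: Sequence[str],
    target: str,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> RegressionReport:
    """LOSO random-forest regression on one clinical score.

    Metrics over pooled out-of-fold predictions: MSE, MAE and explained
    variance ``1 - var(residual) / var(target)`` (NaN for a constant
    target).
    """
    X = _feature_matrix(visits, feature_set)
    y = np.array([float(getattr(v, target)) for v in visits])
    folds = loso_folds(visits)
    n = len(visits)
    yhat = np.zeros(n)
    importances = np.zeros(len(feature_set))
    for train, test in folds.folds:
        tr, te = np.array(train), np.array(test)
        X_tr, X_te = _impute_train_median(X[tr], X[te])
        reg = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        reg.fit(X_tr, y[tr])
        yhat[te] = reg.predict(X_te)
        importances += reg.feature_importances_
    importances /= len(folds.folds)

    resid = y - yhat
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    var_y = float(np.var(y))
    ev = 1.0 - float(np.var(resid)) / var_y if var_y > 0 else float("nan")
    preds_df = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in visits],
            "visit_id": [v.visit_id for v in visits],
            "true": y,
            "predicted": yhat,
        }
    )
    return RegressionReport(
        target=target,
        mse=mse,
        mae=mae,
        explained_variance=ev,
        predictions=preds_df,
        feature_importances=pd.Series(importances, index=list(feature_set)),
    )
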