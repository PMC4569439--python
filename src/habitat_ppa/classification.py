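"""Cross-validated prediction of 12-month survival and molecular subtype.

The top 5 features by coefficient of variation feed a regularized (L2)
logistic model evaluated by stratified threefold cross-validation; the
out-of-fold scores are thresholded at the Youden-optimal ROC cutoff and
summarized as TPR, TNR, ACC = (TP+TN)/(TP+FN+TN+FP) and AUC. Subtype
prediction runs the same machinery one-vs-rest for each of the four
classes (classical, mesenchymal, neural, proneural).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .survival import optimal_cutoff, roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassifierReport:
    task: str
    selected_features: list
    fold_assignments: np.ndarray
    oof_scores: np.ndarray
    cutoff: float
    counts: ConfusionCounts
    auc: float
    tpr: float
    tnr: float
    acc: float
    notes: dict = field(default_factory=dict)


def coefficient_of_variation(feature_column) -> float:
    """|sample sd / sample mean|; NaN when unusable.

    Columns with fewer than 2 non-missing values, or a mean within 1e-12
    of zero (CoV undefined), report NaN and sort last in selection.
    """
    x = np.asarray(feature_column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if abs(m) < 1e-12:
        return float("nan")
    return float(abs(x.std(ddof=1) / m))


def select_top_k(features: pd.DataFrame, k: int = 5) -> list:
    """Feature names with the k largest CoV; ties keep column order."""
    cov = np.array([coefficient_of_variation(features[c])
                    for c in features.columns])
    usable = np.isfinite(cov)
    if usable.sum() < k:
        usable_names = [c for c, u in zip(features.columns, usable) if u]
        raise ValueError(
            f"only {usable.sum()} features have a defined CoV "
            f"(need {k}): {usable_names}")
    order = np.argsort(np.where(usable, -cov, np.inf), kind="stable")
    return [features.columns[i] for i in order[:k]]


def crossval_scores(features: pd.DataFrame, labels, folds: int = 3,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified k-fold out-of-fold probability scores.

    Returns (oof_scores, fold_assignments); deterministic given the seed.
    Missing feature values are imputed with the training-fold mean.
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify "
            f"into {folds} folds")
    X = features.to_numpy(dtype=float)
    oof = np.full(len(y), np.nan)
    assign = np.full(len(y), -1, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = X[tr].copy(), X[te].copy()
        col_mean = np.nanmean(Xtr, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        for M in (Xtr, Xte):
            nan = ~np.isfinite(M)
            M[nan] = np.take(col_mean, np.nonzero(nan)[1])
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=1000))  # L2 by default
        model.fit(Xtr, y[tr])
        oof[te] = model.predict_proba(Xte)[:, 1]
        assign[te] = fold
    return oof, assign


def confusion_metrics(scores, labels,
                      cutoff: float) -> tuple[ConfusionCounts, float, float, float]:
    """Counts and TPR/TNR/ACC at a score cutoff (score >= cutoff -> positive)."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    cc = ConfusionCounts(tp=int(((pred == 1) & (y == 1)).sum()),
                         fp=int(((pred == 1) & (y == 0)).sum()),
                         tn=int(((pred == 0) & (y == 0)).sum()),
                         fn=int(((pred == 0) & (y == 1)).sum()))
    tpr = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else float("nan")
    tnr = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) else float("nan")
    acc = (cc.tp + cc.tn) / cc.total if cc.total else float("nan")
    return cc, tpr, tnr, acc


def evaluate_binary(features: pd.DataFrame, labels, task: str = "os12",
                    k: int = 5, folds: int = 3, seed: int = 0,
                    select: bool = True) -> ClassifierReport:
    """Select top-k CoV features, cross-validate, report Youden-point metrics."""
    selected = select_top_k(features, k=k) if select else list(features.columns)
    oof, assign = crossval_scores(features[selected], labels,
                                  folds=folds, seed=seed)
    roc = roc_curve(oof, labels)
    cutoff = optimal_cutoff(roc)
    counts, tpr, tnr, acc = confusion_metrics(oof, labels, cutoff)
    return ClassifierReport(task=task, selected_features=selected,
                            fold_assignments=assign, oof_scores=oof,
                            cutoff=cutoff, counts=counts, auc=roc.auc,
                            tpr=tpr, tnr=tnr, acc=acc,
                            notes={"classifier": "L2 logistic regression",
                                   "folds": folds, "seed": seed})


def subtype_one_vs_rest(features: pd.DataFrame, subtypes, folds: int = 3,
                        seed: int = 0, k: int = 5) -> dict:
    """One-vs-rest reports per subtype; rare subtypes are skipped with a note."""
    subtypes = np.asarray(subtypes)
    reports: dict = {}
    for s in ("classical", "mesenchymal", "neural", "proneural"):
        y = (subtypes == s).astype(int)
        if y.sum() < folds or (1 - y).sum() < folds:
            reports[s] = None
            continue
        reports[s] = evaluate_binary(features, y, task=f"subtype:{s}",
                                     k=k, folds=folds, seed=seed)
    return reports
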