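"""Repeated cross-validated Gaussian Naive-Bayes classification.

Subjects are partitioned into k folds (stratified by default so that no
training fold loses a class at small group sizes); a Gaussian Naive-Bayes
classifier is trained on k-1 folds and tested on the held-out fold, over
all folds and over many random repartitions.  Accuracy, and per-class
one-vs-rest sensitivity, specificity, precision and ROC AUC (from class
posterior probabilities) are averaged within each repeat; the report
gives mean and standard deviation across repeats, plus
prevalence-weighted averages across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB


@dataclass
class ClassMetrics:
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    precision: tuple[float, float]
    auc: tuple[float, float]


@dataclass
class ClassifierReport:
    accuracy: tuple[float, float]  # (mean, sd) over repeats
    per_class: dict[str, ClassMetrics]
    weighted: ClassMetrics
    classes: list[str] = field(default_factory=list)
    n_repeats: int = 0

    def to_dict(self) -> dict:
        def pair(p):
            return {"mean": p[0], "sd": p[1]}

        return {
            "accuracy": pair(self.accuracy),
            "classes": {
                c: {
                    "sensitivity": pair(m.sensitivity),
                    "specificity": pair(m.specificity),
                    "precision": pair(m.precision),
                    "auc": pair(m.auc),
                }
                for c, m in self.per_class.items()
            },
            "weighted_average": {
                "sensitivity": pair(self.weighted.sensitivity),
                "specificity": pair(self.weighted.specificity),
                "precision": pair(self.weighted.precision),
                "auc": pair(self.weighted.auc),
            },
            "n_repeats": self.n_repeats,
        }


def _one_vs_rest_metrics(y_true, y_pred, proba, classes) -> dict[str, np.ndarray]:
    """Per-class sensitivity/specificity/precision/AUC for one repeat."""
    out = {"sensitivity": [], "specificity": [], "precision": [], "auc": []}
    for ci, c in enumerate(classes):
        pos = y_true == c
        pred_pos = y_pred == c
        tp = float(np.sum(pos & pred_pos))
        fn = float(np.sum(pos & ~pred_pos))
        fp = float(np.sum(~pos & pred_pos))
        tn = float(np.sum(~pos & ~pred_pos))
        out["sensitivity"].append(tp / (tp + fn) if tp + fn > 0 else 0.0)
        out["specificity"].append(tn / (tn + fp) if tn + fp > 0 else 0.0)
        out["precision"].append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        out["auc"].append(roc_auc_score(pos.astype(int), proba[:, ci]))
    return {k: np.asarray(v) for k, v in out.items()}


def nb_crossvalidate(
    features: pd.DataFrame,
    n_folds: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
    label_col: str = "label",
    stratified: bool = True,
) -> ClassifierReport:
    """Repeated k-fold CV of a Gaussian Naive-Bayes classifier.

    ``features`` holds one row per subject: a label column plus numeric
    feature columns (a ``subject_id`` column is ignored if present).
    """
    feat_cols = [c for c in features.columns if c not in (label_col, "subject_id")]
    x = features[feat_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("features must be finite (no missing values)")
    y = features[label_col].to_numpy()
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 subjects")
    if len(y) < n_folds:
        raise ValueError("need at least n_folds subjects")

    rng = np.random.default_rng(seed)
    acc = np.zeros(n_repeats)
    per_rep = {
        k: np.zeros((n_repeats, len(classes)))
        for k in ("sensitivity", "specificity", "precision", "auc")
    }
    for rep in range(n_repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        splitter = (
            StratifiedKFold(n_folds, shuffle=True, random_state=rs)
            if stratified
            else KFold(n_folds, shuffle=True, random_state=rs)
        )
        y_pred = np.empty(len(y), dtype=object)
        proba = np.zeros((len(y), len(classes)))
        for tr, te in splitter.split(x, y):
            clf = GaussianNB()
            clf.fit(x[tr], y[tr])
            p = clf.predict_proba(x[te])
            # align columns to the global class order
            col = {c: k for k, c in enumerate(clf.classes_)}
            for ci, c in enumerate(classes):
                if c in col:
                    proba[te, ci] = p[:, col[c]]
            y_pred[te] = clf.predict(x[te])
        acc[rep] = float(np.mean(y_pred == y))
        m = _one_vs_rest_metrics(y, y_pred, proba, classes)
        for k in per_rep:
            per_rep[k][rep] = m[k]

    prev = np.array([np.mean(y == c) for c in classes])

    def agg(vals: np.ndarray) -> tuple[float, float]:
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    per_class = {}
    for ci, c in enumerate(classes):
        per_class[c] = ClassMetrics(
            sensitivity=agg(per_rep["sensitivity"][:, ci]),
            specificity=agg(per_rep["specificity"][:, ci]),
            precision=agg(per_rep["precision"][:, ci]),
            auc=agg(per_rep["auc"][:, ci]),
        )
    weighted = ClassMetrics(
        **{
            k: agg(per_rep[k] @ prev)
            for k in ("sensitivity", "specificity", "precision", "auc")
        }
    )
    return ClassifierReport(
        accuracy=agg(acc),
        per_class=per_class,
        weighted=weighted,
        classes=classes,
        n_repeats=n_repeats,
    )
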