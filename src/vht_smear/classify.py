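"""Serial feature fusion, classifier variants and the evaluation suite.

Fusion is plain ordered concatenation of two feature vectors.  The
classifier harness reproduces the usual point-and-click toolbox variants:
six SVMs (linear, quadratic, cubic, fine/medium/coarse Gaussian — RBF with
kernel scale sqrt(d)/4, sqrt(d) and 4*sqrt(d) for d features) and three KNNs
(fine k=1, coarse k=100, cosine k=10).  Every variant standardises features
with training statistics only.  Evaluation reports a full one-vs-rest metric
suite per class — sensitivity, specificity, PPV, NPV, accuracy, F- and
G-measure — plus macro averages, the overall accuracy/error and trapezoidal
one-vs-rest ROC AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector

SVM_VARIANTS = ("linear-svm", "quadratic-svm", "cubic-svm",
                "fine-gaussian-svm", "medium-gaussian-svm", "coarse-gaussian-svm")
KNN_VARIANTS = ("fine-knn", "coarse-knn", "cosine-knn")
VARIANTS = SVM_VARIANTS + KNN_VARIANTS


def fuse(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Serial fusion: a's values followed by b's values, order preserved."""
    return FeatureVector(values=np.concatenate([a.values, b.values]),
                         source="fused")


def _rbf_gamma(n_features: int, scale_factor: float) -> float:
    # toolbox convention: K(x,u) = exp(-||x-u||^2 / s^2), s = factor*sqrt(d)
    s = scale_factor * np.sqrt(n_features)
    return 1.0 / (s * s)


def make_classifier(variant: str, n_features: int, seed: int = 0) -> Pipeline:
    """Standardising pipeline for one named classifier variant."""
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; supported: {', '.join(VARIANTS)}")
    svc = dict(C=1.0, decision_function_shape="ovr", random_state=seed)
    if variant == "linear-svm":
        est = SVC(kernel="linear", **svc)
    elif variant == "quadratic-svm":
        est = SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, **svc)
    elif variant == "cubic-svm":
        est = SVC(kernel="poly", degree=3, gamma="scale", coef0=1.0, **svc)
    elif variant == "fine-gaussian-svm":
        est = SVC(kernel="rbf", gamma=_rbf_gamma(n_features, 0.25), **svc)
    elif variant == "medium-gaussian-svm":
        est = SVC(kernel="rbf", gamma=_rbf_gamma(n_features, 1.0), **svc)
    elif variant == "coarse-gaussian-svm":
        est = SVC(kernel="rbf", gamma=_rbf_gamma(n_features, 4.0), **svc)
    elif variant == "fine-knn":
        est = KNeighborsClassifier(n_neighbors=1)
    elif variant == "coarse-knn":
        est = KNeighborsClassifier(n_neighbors=100)
    else:  # cosine-knn
        est = KNeighborsClassifier(n_neighbors=10, metric="cosine")
    return make_pipeline(StandardScaler(), est)


def train_classifier(X, y, variant: str, seed: int = 0) -> Pipeline:
    """Fit one classifier variant on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least two classes")
    model = make_classifier(variant, X.shape[1], seed=seed)
    # KNN neighbor counts cannot exceed the training set size
    knn = model.named_steps.get("kneighborsclassifier")
    if knn is not None and knn.n_neighbors > len(y):
        knn.set_params(n_neighbors=len(y))
    model.fit(X, y)
    return model


@dataclass
class EvalReport:
    """Confusion matrix plus the one-vs-rest metric suite."""

    labels: Tuple[str, ...]
    confusion: np.ndarray  # rows = true, cols = predicted
    per_class: Dict[str, Dict[str, Optional[float]]]
    macro: Dict[str, float]
    overall_accuracy: float
    error: float
    auc: Dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "overall_accuracy": self.overall_accuracy,
            "error": self.error,
            "auc": self.auc,
        }


_METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv",
            "f_measure", "g_measure")


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0  # 0/0 convention


def report_from_confusion(cm: np.ndarray,
                          labels: Sequence[str]) -> EvalReport:
    """Full metric suite from a (true x predicted) count matrix.

    A class absent from both truth and prediction gets ``None`` metrics and
    is excluded from the macro averages.
    """
    cm = np.asarray(cm, dtype=int)
    total = int(cm.sum())
    per_class: Dict[str, Dict[str, Optional[float]]] = {}
    macro_acc: Dict[str, List[float]] = {m: [] for m in _METRICS}
    for i, lab in enumerate(labels):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = total - tp - fn - fp
        if tp + fn + fp == 0:  # class never seen in truth or prediction
            per_class[lab] = {m: None for m in _METRICS}
            continue
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        ppv = _safe_div(tp, tp + fp)
        npv = _safe_div(tn, tn + fn)
        metrics = {
            "accuracy": _safe_div(tp + tn, total),
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "f_measure": _safe_div(2 * ppv * sens, ppv + sens),
            "g_measure": float(np.sqrt(ppv * sens)),
        }
        per_class[lab] = metrics
        for m in _METRICS:
            macro_acc[m].append(metrics[m])
    macro = {m: float(np.mean(v)) if v else 0.0 for m, v in macro_acc.items()}
    overall = _safe_div(int(np.trace(cm)), total)
    return EvalReport(labels=tuple(labels), confusion=cm, per_class=per_class,
                      macro=macro, overall_accuracy=overall,
                      error=1.0 - overall)


def _decision_scores(model, X) -> Optional[np.ndarray]:
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        return s if s.ndim == 2 else np.column_stack([-s, s])
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    return None


def evaluate(model, X_test, y_test,
             labels: Sequence[str] | None = None) -> EvalReport:
    """Evaluate a fitted classifier: confusion matrix, metric suite, OvR AUCs."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    if labels is None:
        labels = [str(c) for c in model.classes_]
    y_pred = model.predict(X_test)
    cm = confusion_matrix(y_test, y_pred, labels=list(labels))
    report = report_from_confusion(cm, labels)
    scores = _decision_scores(model, X_test)
    if scores is not None:
        model_labels = [str(c) for c in model.classes_]
        for lab in labels:
            truth = (y_test.astype(str) == lab).astype(int)
            if lab not in model_labels or truth.min() == truth.max():
                report.auc[lab] = None
                continue
            col = model_labels.index(lab)
            fpr, tpr, _ = roc_curve(truth, scores[:, col])
            report.auc[lab] = float(auc(fpr, tpr))
    return report


def roc_points(model, X_test, y_test, label: str) -> pd.DataFrame:
    """One-vs-rest ROC curve points (fpr, tpr) for one class."""
    scores = _decision_scores(model, np.asarray(X_test, dtype=float))
    model_labels = [str(c) for c in model.classes_]
    truth = (np.asarray(y_test).astype(str) == label).astype(int)
    fpr, tpr, thr = roc_curve(truth, scores[:, model_labels.index(label)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def run_fusion_grid(deep: pd.DataFrame, vht: pd.DataFrame, y: Sequence[str],
                    grid: Sequence[Tuple[int, int]],
                    variants: Sequence[str] = ("cubic-svm",),
                    seed: int = 0,
                    aco_params: dict | None = None,
                    selectors_out: list | None = None) -> pd.DataFrame:
    """Fusion-size sweep: ACO-select deep features, truncate VHT, fuse, score.

    For every ``(k_deep, k_vht)`` grid point the deep table is reduced to
    ``k_deep`` ACO-selected columns, the VHT table truncated to its first
    ``k_vht`` columns (layout order), the two fused, and each classifier
    variant fitted on a stratified, seeded 75/25 split.  Returns one row per
    (grid point, variant) with the headline metrics.
    """
    from .aco import AntColonySelector

    deep_X = deep.to_numpy(dtype=float)
    vht_X = vht.to_numpy(dtype=float)
    y = np.asarray(y)
    aco_params = dict(aco_params or {})
    rows = []
    for gi, (k_deep, k_vht) in enumerate(grid):
        if k_vht > vht_X.shape[1]:
            raise ValueError(f"k_vht={k_vht} exceeds {vht_X.shape[1]} VHT features")
        if k_deep > deep_X.shape[1]:
            raise ValueError(f"k_deep={k_deep} exceeds {deep_X.shape[1]} deep features")
        sel = AntColonySelector(k=k_deep, seed=seed + gi, **aco_params)
        sel.fit(deep_X, y)
        if selectors_out is not None:
            selectors_out.append(sel)
        fused = np.hstack([sel.transform(deep_X), vht_X[:, :k_vht]])
        X_tr, X_te, y_tr, y_te = train_test_split(
            fused, y, test_size=0.25, stratify=y, random_state=seed)
        for variant in variants:
            model = train_classifier(X_tr, y_tr, variant, seed=seed)
            rep = evaluate(model, X_te, y_te)
            rows.append({
                "k_deep": k_deep, "k_vht": k_vht,
                "fused_length": k_deep + k_vht, "variant": variant,
                "accuracy": rep.overall_accuracy,
                "sensitivity": rep.macro["sensitivity"],
                "specificity": rep.macro["specificity"],
                "ppv": rep.macro["ppv"], "npv": rep.macro["npv"],
                "error": rep.error,
            })
    return pd.DataFrame(rows, columns=["k_deep", "k_vht", "fused_length",
                                       "variant", "accuracy", "sensitivity",
                                       "specificity", "ppv", "npv", "error"])
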