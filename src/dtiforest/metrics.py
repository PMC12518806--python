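"""Multi-class evaluation metrics and confusion matrices.

The report covers accuracy, macro (or micro) precision / recall / F1 /
F2, Cohen's kappa, one-vs-rest macro AUC-ROC, and error metrics
(RMSE / MSE / MAE) computed on integer class codes — a reporting
convention for classification tasks, not a modelling choice. F2 is the
F-beta measure at beta = 2, weighting recall four times as heavily as
precision: F2 = 5PR / (4P + R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "f2_from_precision_recall",
]


def confusion_matrix(
    y_true: Sequence,
    y_pred: Sequence,
    classes: Optional[Sequence] = None,
) -> np.ndarray:
    """Entry (a, b) counts samples of true class a predicted as b."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    known = set(classes.tolist())
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        extra = set(arr.tolist()) - known
        if extra:
            raise ValueError(f"{name} contains labels outside classes: {extra}")
    return _skm.confusion_matrix(y_true, y_pred, labels=classes)


def f2_from_precision_recall(precision: float, recall: float) -> float:
    """F2 = 5 * P * R / (4 * P + R)."""
    denom = 4.0 * precision + recall
    if denom == 0:
        return 0.0
    return 5.0 * precision * recall / denom


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    f2: float
    kappa: float
    auc_roc: Optional[float]
    rmse: float
    mse: float
    mae: float
    confusion: np.ndarray
    per_class: dict
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f2": self.f2,
            "kappa": self.kappa,
            "auc_roc": self.auc_roc,
            "rmse": self.rmse,
            "mse": self.mse,
            "mae": self.mae,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "averaging": self.averaging,
        }


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    y_proba: Optional[np.ndarray] = None,
    averaging: str = "macro",
    classes: Optional[Sequence] = None,
) -> MetricsReport:
    """Full evaluation report.

    ``y_proba`` (n x n_classes, columns aligned with sorted classes) is
    needed for AUC-ROC; with a single observed true class the AUC is
    undefined and reported as None with a warning. Error metrics use the
    integer code of each label in the (sorted) class list.
    """
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    conf = confusion_matrix(y_true, y_pred, classes)

    acc = float(_skm.accuracy_score(y_true, y_pred))
    prec = float(_skm.precision_score(
        y_true, y_pred, labels=classes, average=averaging, zero_division=0))
    rec = float(_skm.recall_score(
        y_true, y_pred, labels=classes, average=averaging, zero_division=0))
    f1 = float(_skm.f1_score(
        y_true, y_pred, labels=classes, average=averaging, zero_division=0))
    f2 = float(_skm.fbeta_score(
        y_true, y_pred, beta=2.0, labels=classes, average=averaging,
        zero_division=0))
    kappa = float(_skm.cohen_kappa_score(y_true, y_pred, labels=classes))

    auc: Optional[float] = None
    if y_proba is not None:
        y_proba = np.asarray(y_proba, dtype=float)
        present = np.unique(y_true)
        if present.size < 2:
            warnings.warn("AUC undefined for single-class y_true; "
                          "reported as missing")
        elif present.size < classes.size:
            # one-vs-rest macro over classes actually present
            aucs = []
            for k, c in enumerate(classes):
                yb = (y_true == c).astype(int)
                if yb.min() == yb.max():
                    continue
                aucs.append(_skm.roc_auc_score(yb, y_proba[:, k]))
            auc = float(np.mean(aucs)) if aucs else None
        elif classes.size == 2:
            auc = float(_skm.roc_auc_score(
                (y_true == classes[1]).astype(int), y_proba[:, 1]))
        else:
            auc = float(_skm.roc_auc_score(
                y_true, y_proba, labels=classes,
                multi_class="ovr", average="macro"))

    code = {c: k for k, c in enumerate(classes.tolist())}
    t = np.array([code[v] for v in y_true.tolist()], dtype=float)
    p = np.array([code[v] for v in y_pred.tolist()], dtype=float)
    mse = float(np.mean((t - p) ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(t - p)))

    per_class = {}
    pc_prec, pc_rec, pc_f1, _ = _skm.precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    for k, c in enumerate(classes.tolist()):
        per_class[str(c)] = {
            "precision": float(pc_prec[k]),
            "recall": float(pc_rec[k]),
            "f1": float(pc_f1[k]),
            "support": int(conf[k].sum()),
        }

    return MetricsReport(
        accuracy=acc, precision=prec, recall=rec, f1=f1, f2=f2,
        kappa=kappa, auc_roc=auc, rmse=rmse, mse=mse, mae=mae,
        confusion=conf, per_class=per_class, averaging=averaging,
    )
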