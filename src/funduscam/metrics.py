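"""Multi-class DR-grading performance suite.

From a 5x5 confusion matrix (rows = true grade, columns = predicted):
accuracy, Cohen's kappa, the multi-class Matthews correlation, and macro
one-vs-rest sensitivity / specificity / PPV / NPV; macro one-vs-rest ROC
AUC from per-image probability scores; and per-grade SE/SP. One-vs-rest
entries with a zero denominator are undefined (NaN) and excluded from
macro means with a warning — never imputed as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

N_GRADES = 5

__all__ = ["MetricsReport", "confusion", "per_grade_se_sp", "overall_metrics",
           "roc_points"]


@dataclass
class MetricsReport:
    accuracy: float
    auc: float
    kappa: float
    matthews: float
    se: float
    sp: float
    ppv: float
    npv: float
    per_grade: pd.DataFrame = field(repr=False)
    aggregation: str = "macro one-vs-rest; undefined entries excluded"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "auc", "kappa", "matthews", "se", "sp", "ppv", "npv")}
        d["aggregation"] = self.aggregation
        d["per_grade"] = {
            int(g): {"se": row["se"], "sp": row["sp"]}
            for g, row in self.per_grade.set_index("grade").iterrows()
        }
        return d


def confusion(true_grades, predicted_grades) -> np.ndarray:
    true_grades = np.asarray(true_grades, dtype=int)
    predicted_grades = np.asarray(predicted_grades, dtype=int)
    if true_grades.size == 0:
        raise ValueError("empty input")
    if true_grades.shape != predicted_grades.shape:
        raise ValueError("length mismatch")
    for arr, what in ((true_grades, "true"), (predicted_grades, "predicted")):
        if arr.min() < 0 or arr.max() >= N_GRADES:
            raise ValueError(f"{what} grade out of range 0-{N_GRADES - 1}")
    return _sk_confusion(true_grades, predicted_grades, labels=np.arange(N_GRADES))


def _ovr_counts(cm: np.ndarray, g: int) -> tuple[int, int, int, int]:
    tp = cm[g, g]
    fn = cm[g, :].sum() - tp
    fp = cm[:, g].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(fp), int(tn), int(fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def per_grade_se_sp(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest sensitivity and specificity per grade (NaN if undefined)."""
    rows = []
    for g in range(N_GRADES):
        tp, fp, tn, fn = _ovr_counts(cm, g)
        rows.append({"grade": g,
                     "se": _safe_div(tp, tp + fn),
                     "sp": _safe_div(tn, tn + fp)})
    return pd.DataFrame(rows)


def _kappa(cm: np.ndarray) -> float:
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) / n) @ (cm.sum(axis=1) / n))
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _matthews(cm: np.ndarray) -> float:
    # multi-class generalization from the confusion matrix
    t = cm.sum(axis=1).astype(float)   # true-class totals
    p = cm.sum(axis=0).astype(float)   # predicted-class totals
    c = np.trace(cm).astype(float)
    s = cm.sum().astype(float)
    num = c * s - t @ p
    den = np.sqrt((s**2 - p @ p) * (s**2 - t @ t))
    return float(num / den) if den > 0 else 0.0


def _macro(values: list[float], what: str) -> float:
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        warnings.warn(f"undefined one-vs-rest {what} entries excluded from macro mean",
                      stacklevel=3)
    return float(np.nanmean(arr)) if not np.isnan(arr).all() else np.nan


def _macro_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    aucs = []
    for g in range(N_GRADES):
        pos = y_true == g
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, scores[:, g]))
        else:
            aucs.append(np.nan)
    return _macro(aucs, "AUC")


def overall_metrics(cm: np.ndarray, y_true=None, scores=None) -> MetricsReport:
    """Full Table-style report from a confusion matrix and, when provided,
    per-image probability scores for the ROC AUC."""
    cm = np.asarray(cm)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    se_list, sp_list, ppv_list, npv_list = [], [], [], []
    for g in range(N_GRADES):
        tp, fp, tn, fn = _ovr_counts(cm, g)
        se_list.append(_safe_div(tp, tp + fn))
        sp_list.append(_safe_div(tn, tn + fp))
        ppv_list.append(_safe_div(tp, tp + fp))
        npv_list.append(_safe_div(tn, tn + fn))
    auc = np.nan
    if scores is not None:
        y_true = np.asarray(y_true, dtype=int)
        scores = np.asarray(scores, dtype=float)
        if len(y_true) != n:
            raise ValueError("scores length inconsistent with confusion matrix total")
        auc = _macro_auc(y_true, scores)
    return MetricsReport(
        accuracy=float(np.trace(cm) / n),
        auc=auc,
        kappa=_kappa(cm),
        matthews=_matthews(cm),
        se=_macro(se_list, "SE"),
        sp=_macro(sp_list, "SP"),
        ppv=_macro(ppv_list, "PPV"),
        npv=_macro(npv_list, "NPV"),
        per_grade=per_grade_se_sp(cm),
    )


def roc_points(y_true, scores) -> pd.DataFrame:
    """One-vs-rest ROC curve points per grade, tidy format for CSV export."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    frames = []
    for g in range(N_GRADES):
        pos = y_true == g
        if not (pos.any() and (~pos).any()):
            continue
        fpr, tpr, thr = roc_curve(pos, scores[:, g])
        frames.append(pd.DataFrame({"grade": g, "fpr": fpr, "tpr": tpr,
                                    "threshold": thr}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["grade", "fpr", "tpr", "threshold"])
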