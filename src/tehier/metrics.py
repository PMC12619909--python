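"""Flat per-node and hierarchical evaluation metrics.

Flat metrics summarise one parent-node classifier: confusion matrix,
accuracy, per-class precision / recall / F1, their unweighted (macro)
means, and the Matthews correlation coefficient.  MCC is the primary
benchmark statistic because it stays informative under the heavy class
imbalance typical of repeat libraries; the multiclass form used here
reduces to the familiar binary formula

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

at two classes.

Hierarchical metrics score full prediction paths.  For sample i let P_i
be the most specific predicted label plus its ancestors, and T_i the
true label plus its ancestors; then

    hP = sum_i |P_i ∩ T_i| / sum_i |P_i|
    hR = sum_i |P_i ∩ T_i| / sum_i |T_i|
    hF = harmonic mean of hP and hR.

The universal root is excluded from P_i and T_i by default (every sample
shares it, so including it inflates both scores uniformly); pass
``include_root=True`` for the strict ancestor-set form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import matthews_corrcoef as _sk_mcc

from .hierarchy import Taxonomy

__all__ = ["ConfusionSummary", "HierEvalReport", "flat_metrics", "hier_metrics"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    """Confusion matrix plus the derived flat metrics for one classifier."""

    matrix: pd.DataFrame          # rows = true class, columns = predicted
    accuracy: float
    precision: dict[str, float]   # per class
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("accuracy", self.accuracy),
                ("macro_precision", self.macro_precision),
                ("macro_recall", self.macro_recall),
                ("macro_f1", self.macro_f1),
                ("mcc", self.mcc)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def flat_metrics(true_labels, predicted_labels, label_order: list[str]) -> ConfusionSummary:
    """Confusion matrix and derived metrics over a fixed label order.

    Classes never predicted get precision 0 (logged); macro averages are
    unweighted means over ``label_order``.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if not true_labels or len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must be non-empty and equal-length")
    unknown = (set(true_labels) | set(predicted_labels)) - set(label_order)
    if unknown:
        raise ValueError(f"labels outside label_order: {sorted(unknown)!r}")

    cm = _sk_confusion(true_labels, predicted_labels, labels=label_order)
    matrix = pd.DataFrame(cm, index=label_order, columns=label_order)

    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(label_order):
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        true_pos = cm[i, :].sum()
        if pred_pos == 0:
            logger.info("class %r has zero predicted positives; precision set to 0", lab)
        precision[lab] = tp / pred_pos if pred_pos else 0.0
        recall[lab] = tp / true_pos if true_pos else 0.0
        denom = precision[lab] + recall[lab]
        f1[lab] = 2 * precision[lab] * recall[lab] / denom if denom else 0.0

    n_classes = len(label_order)
    return ConfusionSummary(
        matrix=matrix,
        accuracy=np.trace(cm) / cm.sum(),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=sum(precision.values()) / n_classes,
        macro_recall=sum(recall.values()) / n_classes,
        macro_f1=sum(f1.values()) / n_classes,
        mcc=float(_sk_mcc(true_labels, predicted_labels)),
    )


@dataclass
class HierEvalReport:
    hP: float
    hR: float
    hF: float
    intersection_sizes: list[int]   # |P_i ∩ T_i| per sample


def _ancestor_set(path: list[str], tax: Taxonomy, include_root: bool) -> set[str]:
    full = tax.ancestors(path[-1])
    if full[: len(path)] != [tax.resolve(p) for p in path]:
        raise ValueError(f"path {path!r} is not a root-first taxonomy path")
    labels = set(path)
    if not include_root:
        labels.discard(tax.root)
    return labels


def hier_metrics(pred_paths, true_paths, tax: Taxonomy,
                 include_root: bool = False) -> HierEvalReport:
    """Hierarchical precision / recall / F over ancestor-closed label sets.

    Each path is a root-first label list (a `PredictionPath.labels` or a
    taxonomy `ancestors()` result).  Sums run over samples, micro-style.
    """
    pred_paths = list(pred_paths)
    true_paths = list(true_paths)
    if len(pred_paths) != len(true_paths):
        raise ValueError("prediction and truth path lists differ in length")
    inter_total = pred_total = true_total = 0
    intersections: list[int] = []
    for p_path, t_path in zip(pred_paths, true_paths):
        p_set = _ancestor_set(list(p_path), tax, include_root)
        t_set = _ancestor_set(list(t_path), tax, include_root)
        inter = len(p_set & t_set)
        intersections.append(inter)
        inter_total += inter
        pred_total += len(p_set)
        true_total += len(t_set)
    if pred_total == 0:
        logger.info("no predicted labels below the root; hP set to 0")
    hp = inter_total / pred_total if pred_total else 0.0
    hr = inter_total / true_total if true_total else 0.0
    hf = 2 * hp * hr / (hp + hr) if (hp + hr) else 0.0
    return HierEvalReport(hP=hp, hR=hr, hF=hf, intersection_sizes=intersections)
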