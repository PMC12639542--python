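"""Classification metrics and confusion matrices for all pipeline models.

Binary metrics are computed from TP/FP/TN/FN counts: accuracy,
precision, recall, F1, Matthews correlation coefficient and true
negative rate (specificity).  Multi-class scoring reports a row=gold /
column=predicted confusion matrix and per-class one-vs-rest metrics
with macro (default) or micro averaging.  Any ratio with a zero
denominator is reported as 0.0 and flagged, rather than raising.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionCounts:
    """k x k count matrix; rows are gold labels, columns predictions."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if (self.matrix < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def binary_counts(self, positive) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, TN, FN) for ``positive``."""
        i = self.labels.index(positive)
        tp = int(self.matrix[i, i])
        fp = int(self.matrix[:, i].sum()) - tp
        fn = int(self.matrix[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    tnr: float
    averaging: str
    confusion: ConfusionCounts
    per_class: dict = field(default_factory=dict)
    undefined: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
            "tnr": self.tnr, "averaging": self.averaging,
            "labels": [str(l) for l in self.confusion.labels],
            "confusion": self.confusion.matrix.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "undefined": list(self.undefined),
        }


def _safe_div(num: float, den: float, flag: str, undefined: list) -> float:
    if den == 0:
        undefined.append(flag)
        return 0.0
    return num / den


def confusion_matrix(gold: list, predicted: list, labels: list) -> ConfusionCounts:
    """Tally the row=gold, column=predicted count matrix."""
    if len(gold) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for g, p in zip(gold, predicted):
        if g not in index:
            raise ValueError(f"unknown gold label {g!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        mat[index[g], index[p]] += 1
    return ConfusionCounts(labels=list(labels), matrix=mat)


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy, P, R, F1, MCC and TNR from binary counts."""
    undefined: list[str] = []
    total = tp + fp + tn + fn
    acc = _safe_div(tp + tn, total, "accuracy", undefined)
    p = _safe_div(tp, tp + fp, "precision", undefined)
    r = _safe_div(tp, tp + fn, "recall", undefined)
    f1 = _safe_div(2 * p * r, p + r, "f1", undefined)
    tnr = _safe_div(tn, tn + fp, "tnr", undefined)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", undefined)
    return {"accuracy": acc, "precision": p, "recall": r, "f1": f1,
            "mcc": mcc, "tnr": tnr, "undefined": undefined}


def multiclass_mcc(counts: ConfusionCounts) -> float:
    """Generalized MCC from a k x k confusion matrix."""
    C = counts.matrix.astype(np.float64)
    n = C.sum()
    t = C.sum(axis=1)  # gold counts
    p = C.sum(axis=0)  # predicted counts
    cov = np.trace(C) * n - t @ p
    den = math.sqrt(max(n * n - p @ p, 0.0)) * math.sqrt(max(n * n - t @ t, 0.0))
    if den == 0:
        return 0.0
    return float(cov / den)


def score(gold: list, predicted: list, labels: list | None = None,
          positive=1, averaging: str = "macro") -> MetricReport:
    """Full metric report for aligned gold/predicted label lists.

    With two labels the positive class drives P/R/F1/TNR/MCC; with more,
    per-class one-vs-rest metrics are combined by ``averaging`` and MCC
    uses its multi-class generalization.
    """
    if len(gold) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted"
        )
    if averaging not in ("macro", "micro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    if labels is None:
        labels = sorted(set(gold) | set(predicted), key=str)
    counts = confusion_matrix(gold, predicted, labels)
    undefined: list[str] = []
    acc = _safe_div(float(np.trace(counts.matrix)), counts.total,
                    "accuracy", undefined)

    per_class: dict = {}
    for lab in labels:
        tp, fp, tn, fn = counts.binary_counts(lab)
        per_class[lab] = binary_metrics(tp, fp, tn, fn)

    if len(labels) == 2 and positive in labels:
        m = per_class[positive]
        report = MetricReport(
            accuracy=acc, precision=m["precision"], recall=m["recall"],
            f1=m["f1"], mcc=m["mcc"], tnr=m["tnr"], averaging="binary",
            confusion=counts, per_class=per_class,
            undefined=undefined + m["undefined"],
        )
        return report

    if averaging == "macro":
        prec = float(np.mean([per_class[l]["precision"] for l in labels]))
        rec = float(np.mean([per_class[l]["recall"] for l in labels]))
        f1 = float(np.mean([per_class[l]["f1"] for l in labels]))
        tnr = float(np.mean([per_class[l]["tnr"] for l in labels]))
    else:  # micro
        tps = fps = tns = fns = 0
        for lab in labels:
            tp, fp, tn, fn = counts.binary_counts(lab)
            tps, fps, tns, fns = tps + tp, fps + fp, tns + tn, fns + fn
        m = binary_metrics(tps, fps, tns, fns)
        prec, rec, f1, tnr = m["precision"], m["recall"], m["f1"], m["tnr"]
        undefined += m["undefined"]
    return MetricReport(
        accuracy=acc, precision=prec, recall=rec, f1=f1,
        mcc=multiclass_mcc(counts), tnr=tnr, averaging=averaging,
        confusion=counts, per_class=per_class, undefined=undefined,
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def error_rate_table(per_type_counts: list[tuple[str, int, int]]) -> list[dict]:
    """Per-relation-type error statistics: (type, total, errors) rows.

    Error percentage is ``100 * errors / total`` rounded to 2 decimals;
    rows with zero total are flagged instead of dividing.
    """
    rows = []
    for rtype, total, errors in per_type_counts:
        if errors > total:
            raise ValueError(f"{rtype}: errors {errors} exceed total {total}")
        if total == 0:
            rows.append({"type": rtype, "total": 0, "errors": errors,
                         "error_pct": 0.0, "flagged": True})
        else:
            rows.append({"type": rtype, "total": total, "errors": errors,
                         "error_pct": round(100.0 * errors / total, 2),
                         "flagged": False})
    return rows


def write_report_json(report: MetricReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_json(), fh, indent=1)


def write_confusion_csv(counts: ConfusionCounts, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gold\\predicted"] + [str(l) for l in counts.labels])
        for lab, row in zip(counts.labels, counts.matrix):
            writer.writerow([str(lab)] + row.tolist())


__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_matrix",
    "binary_metrics",
    "multiclass_mcc",
    "score",
    "f1_from_pr",
    "error_rate_table",
    "write_report_json",
    "write_confusion_csv",
]
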