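"""Confusion-matrix construction and per-class Se/Sp/+p/Acc metrics.

The evaluation follows the AAMI convention: a 5x5 confusion matrix with
rows = true classes (N, S, V, F, Q) and columns = predicted classes,
from which one-vs-rest counts are derived per class in the standard
orientation (FN = off-diagonal of the class row, FP = off-diagonal of
the class column), then

    Se  = TP / (TP + FN)          sensitivity (recall)
    Sp  = TN / (TN + FP)          specificity
    +p  = TP / (TP + FP)          positive predictivity (precision)
    Acc = (TP + TN) / total       per-class accuracy

and overall accuracy = trace / total.  Percentages are rounded half-up
to two decimals; a zero-denominator metric is reported as undefined
(``None``), never silently as 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "AAMI_CLASSES",
    "ClassMetrics",
    "ClassMetricsReport",
    "confusion",
    "metrics",
    "one_vs_rest_counts",
    "report",
]

#: Canonical AAMI class order (rows/columns of every confusion matrix).
AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")


def confusion(
    true_labels,
    predicted_labels,
    classes: tuple[str, ...] = AAMI_CLASSES,
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    if true_labels.size == 0:
        return np.zeros((len(classes), len(classes)), dtype=int)
    known = set(classes)
    for arr, what in ((true_labels, "true"), (predicted_labels, "predicted")):
        bad = [x for x in arr if x not in known]
        if bad:
            raise ValueError(f"unknown {what} label {bad[0]!r}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(classes))


def one_vs_rest_counts(cm: np.ndarray, class_k: int) -> tuple[int, int, int, int]:
    """``(TP, FP, TN, FN)`` for class ``class_k`` against the rest."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = int(cm[class_k, class_k])
    fn = int(cm[class_k].sum() - tp)
    fp = int(cm[:, class_k].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, fp, tn, fn


def _pct(num: int, den: int) -> float | None:
    """Percentage num/den rounded half-up to 2 decimals; None if den=0."""
    if den == 0:
        return None
    q = (Decimal(100 * num) / Decimal(den)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    se: float | None
    sp: float | None
    ppv: float | None
    acc: float | None


@dataclass(frozen=True)
class ClassMetricsReport:
    classes: tuple[str, ...]
    confusion: tuple[tuple[int, ...], ...]
    per_class: dict[str, ClassMetrics]
    overall_accuracy: float

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "classes": list(self.classes),
            "confusion": [list(r) for r in self.confusion],
            "per_class": {
                k: dataclasses.asdict(v) for k, v in self.per_class.items()
            },
            "overall_accuracy": self.overall_accuracy,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassMetricsReport":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            confusion=tuple(tuple(int(x) for x in r) for r in d["confusion"]),
            per_class={k: ClassMetrics(**v) for k, v in d["per_class"].items()},
            overall_accuracy=d["overall_accuracy"],
        )


def metrics(
    cm: np.ndarray,
    classes: tuple[str, ...] = AAMI_CLASSES,
) -> ClassMetricsReport:
    """Per-class and overall metrics from a confusion matrix."""
    cm = np.asarray(cm, dtype=int)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    per: dict[str, ClassMetrics] = {}
    for k, name in enumerate(classes):
        tp, fp, tn, fn = one_vs_rest_counts(cm, k)
        per[name] = ClassMetrics(
            tp=tp,
            tn=tn,
            fp=fp,
            fn=fn,
            se=_pct(tp, tp + fn),
            sp=_pct(tn, tn + fp),
            ppv=_pct(tp, tp + fp),
            acc=_pct(tp + tn, total),
        )
    overall = _pct(int(np.trace(cm)), total)
    assert overall is not None
    return ClassMetricsReport(
        classes=tuple(classes),
        confusion=tuple(tuple(int(x) for x in row) for row in cm),
        per_class=per,
        overall_accuracy=overall,
    )


def _fmt(v: float | None) -> str:
    return "--" if v is None else f"{v:.2f}"


def report(cmr: ClassMetricsReport, destination=None) -> str:
    """Render a report as a text table (and optionally write text+JSON).

    ``destination`` may be a path prefix: ``<prefix>.txt`` and
    ``<prefix>.json`` are written.  Returns the text table either way.
    """
    classes = cmr.classes
    header = (
        ["true"]
        + [c.lower() for c in classes]
        + ["TP", "TN", "FP", "FN", "Se", "Sp", "+p", "Acc"]
    )
    lines = ["\t".join(header)]
    for i, c in enumerate(classes):
        m = cmr.per_class[c]
        row = (
            [c]
            + [str(x) for x in cmr.confusion[i]]
            + [str(m.tp), str(m.tn), str(m.fp), str(m.fn)]
            + [_fmt(m.se), _fmt(m.sp), _fmt(m.ppv), _fmt(m.acc)]
        )
        lines.append("\t".join(row))
    lines.append(f"overall accuracy (%)\t{cmr.overall_accuracy:.2f}")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        prefix = str(destination)
        try:
            with open(prefix + ".txt", "w", encoding="utf-8") as fh:
                fh.write(text)
            with open(prefix + ".json", "w", encoding="utf-8") as fh:
                fh.write(cmr.to_json())
        except OSError as exc:
            raise OSError(f"cannot write report to {prefix!r}: {exc}") from exc
    return text
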