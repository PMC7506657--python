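"""Classification metrics and the shared report schema.

Both the shallow and the CNN pipelines produce the same
:class:`EvaluationReport`: per-class precision / recall / F-measure with
supports, overall accuracy, macro and support-weighted averages, the
population standard deviation of the five per-class F-measures (the
spread statistic printed alongside weighted averages), and the confusion
matrix.  Zero denominators yield 0 and are flagged in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn import metrics as skm

from stepgait.signal_model import GaitActivity

_CLASS_CODES = [int(a) for a in GaitActivity]


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when P + R = 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean over classes."""
    return float(np.mean(values))


def weighted_average(values: Sequence[float], supports: Sequence[int]) -> float:
    """Support-weighted mean over classes."""
    values = np.asarray(values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    return float(np.sum(values * supports) / np.sum(supports))


def f_spread(f_values: Sequence[float]) -> float:
    """Population standard deviation of the per-class F-measures."""
    return float(np.std(np.asarray(f_values, dtype=float)))


@dataclass
class EvaluationReport:
    """Per-class and aggregate classification metrics for the five activities."""

    precision: dict[GaitActivity, float]
    recall: dict[GaitActivity, float]
    f_measure: dict[GaitActivity, float]
    support: dict[GaitActivity, int]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    f_sigma: float
    confusion: np.ndarray
    zero_division_flags: list[str] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.support.values()))

    def to_dict(self) -> dict[str, Any]:
        per_class = {
            a.name: {
                "precision": self.precision[a],
                "recall": self.recall[a],
                "f_measure": self.f_measure[a],
                "support": self.support[a],
            }
            for a in GaitActivity
        }
        return {
            "per_class": per_class,
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "f_sigma": self.f_sigma,
            "confusion": self.confusion.tolist(),
            "zero_division_flags": self.zero_division_flags,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "EvaluationReport":
        per_class = data["per_class"]
        return cls(
            precision={a: per_class[a.name]["precision"] for a in GaitActivity},
            recall={a: per_class[a.name]["recall"] for a in GaitActivity},
            f_measure={a: per_class[a.name]["f_measure"] for a in GaitActivity},
            support={a: per_class[a.name]["support"] for a in GaitActivity},
            accuracy=data["accuracy"],
            macro_avg=data["macro_avg"],
            weighted_avg=data["weighted_avg"],
            f_sigma=data["f_sigma"],
            confusion=np.asarray(data["confusion"]),
            zero_division_flags=list(data.get("zero_division_flags", [])),
            metadata=dict(data.get("metadata", {})),
        )


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], normalized: bool = False
) -> np.ndarray:
    """5x5 confusion matrix by (true, predicted).

    The normalized form divides each row by its sum; rows with zero support
    stay all-zero.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    cm = skm.confusion_matrix(y_true, y_pred, labels=_CLASS_CODES).astype(float)
    if normalized:
        row_sums = cm.sum(axis=1, keepdims=True)
        np.divide(cm, row_sums, out=cm, where=row_sums > 0)
    return cm


def attractor_statistic(confusion: np.ndarray) -> np.ndarray:
    """Per-class attraction: column sum of the row-normalized matrix minus 1.

    Positive values mark *attractor* classes (receiving more predictions than
    their expected share); negative values mark *repellers*.
    """
    confusion = np.asarray(confusion, dtype=float)
    row_sums = confusion.sum(axis=1, keepdims=True)
    normed = np.divide(
        confusion, row_sums, out=np.zeros_like(confusion), where=row_sums > 0
    )
    return normed.sum(axis=0) - 1.0


def classification_report(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    metadata: dict[str, Any] | None = None,
) -> EvaluationReport:
    """Full evaluation report over the five gait activities."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    prec, rec, f1, supp = skm.precision_recall_fscore_support(
        y_true, y_pred, labels=_CLASS_CODES, zero_division=0
    )
    flags = []
    for a, code in zip(GaitActivity, _CLASS_CODES):
        if np.sum(y_pred == code) == 0:
            flags.append(f"no predictions for {a.name}: precision set to 0")
        if np.sum(y_true == code) == 0:
            flags.append(f"no instances of {a.name}: recall set to 0")
    accuracy = float(skm.accuracy_score(y_true, y_pred))
    macro = {
        "precision": macro_average(prec),
        "recall": macro_average(rec),
        "f_measure": macro_average(f1),
    }
    weighted = {
        "precision": weighted_average(prec, supp),
        "recall": weighted_average(rec, supp),
        "f_measure": weighted_average(f1, supp),
    }
    return EvaluationReport(
        precision={a: float(p) for a, p in zip(GaitActivity, prec)},
        recall={a: float(r) for a, r in zip(GaitActivity, rec)},
        f_measure={a: float(f) for a, f in zip(GaitActivity, f1)},
        support={a: int(s) for a, s in zip(GaitActivity, supp)},
        accuracy=accuracy,
        macro_avg=macro,
        weighted_avg=weighted,
        f_sigma=f_spread(f1),
        confusion=confusion_matrix(y_true, y_pred),
        zero_division_flags=flags,
        metadata=metadata or {},
    )


def compare_reports(reports: Sequence[EvaluationReport]) -> dict[str, Any]:
    """Side-by-side summary of per-class F-measure distributions.

    For each report: the median and spread of the five per-class F-measures,
    plus accuracy and the weighted F — the quantities used to compare
    treatments and approaches.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for rep in reports:
        f_values = [rep.f_measure[a] for a in GaitActivity]
        rows.append(
            {
                "metadata": dict(rep.metadata),
                "f_median": float(np.median(f_values)),
                "f_sigma": rep.f_sigma,
                "f_min": float(np.min(f_values)),
                "f_max": float(np.max(f_values)),
                "accuracy": rep.accuracy,
                "weighted_f": rep.weighted_avg["f_measure"],
            }
        )
    return {"reports": rows}
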