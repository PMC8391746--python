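"""Quantitative evaluation: confusion matrices, macro metrics, the
label-efficiency protocol, and color-codable per-record quality tracks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .calibrate import QualityThresholds, classify, find_thresholds, subsample_labels
from .records import GRADE_NAMES, SignalRecord

__all__ = [
    "EvalReport",
    "score_report",
    "label_efficiency_experiment",
    "QualityTrack",
    "build_quality_track",
]

_CLASSES = (0, 1, 2)


@dataclass
class EvalReport:
    """Triclassification metrics (rows of the confusion matrix = true)."""

    confusion: np.ndarray
    accuracy: float
    per_class: dict          # grade -> {precision, recall, f1, support}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": {GRADE_NAMES[c]: v for c, v in self.per_class.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n": self.n,
        }

    def __str__(self) -> str:
        lines = [
            f"n = {self.n}   accuracy = {self.accuracy:.4f}",
            f"macro precision/recall/F1 = "
            f"{self.macro_precision:.4f} / {self.macro_recall:.4f} / {self.macro_f1:.4f}",
            "confusion (rows=true good/acceptable/unacceptable):",
        ]
        for row in self.confusion:
            lines.append("  " + "  ".join(f"{v:6d}" for v in row))
        return "\n".join(lines)


def score_report(true_labels, pred_labels) -> EvalReport:
    """Confusion matrix, accuracy and macro precision/recall/F1.

    Macro metrics are unweighted means over the three grades; a class
    with zero denominator contributes 0.
    """
    y, p = np.asarray(true_labels, int), np.asarray(pred_labels, int)
    if len(y) != len(p) or len(y) == 0:
        raise ValueError("label arrays must be equal-length and non-empty")
    cm = confusion_matrix(y, p, labels=_CLASSES)
    prec, rec, f1, support = precision_recall_fscore_support(
        y, p, labels=_CLASSES, zero_division=0
    )
    per_class = {
        c: {
            "precision": float(prec[c]), "recall": float(rec[c]),
            "f1": float(f1[c]), "support": int(support[c]),
        }
        for c in _CLASSES
    }
    return EvalReport(
        confusion=cm,
        accuracy=float(np.trace(cm)) / len(y),
        per_class=per_class,
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        n=len(y),
    )


def label_efficiency_experiment(
    val_scores,
    val_labels,
    test_scores,
    test_labels,
    ns=(200, 600, 1000),
    repeats: int = 30,
    seed: int = 0,
    test_flatline=None,
) -> pd.DataFrame:
    """How calibration quality depends on the number of labels.

    Per repeat: draw n validation labels uniformly without replacement,
    fit thresholds on them, classify the full test set, record accuracy.
    Returns one row per n with mean and SD over repeats.
    """
    val_scores = np.asarray(val_scores, float)
    val_labels = np.asarray(val_labels, int)
    test_labels = np.asarray(test_labels, int)
    if max(ns) > len(val_labels):
        raise ValueError(f"need at least {max(ns)} labels, have {len(val_labels)}")
    rows = []
    for n in ns:
        accs = []
        for r in range(repeats):
            idx = subsample_labels(len(val_labels), n, seed=seed * 100003 + r * 1009 + n)
            thr = find_thresholds(val_scores[idx], val_labels[idx])
            pred = classify(test_scores, thr, flatline=test_flatline)
            accs.append(float(np.mean(pred == test_labels)))
        accs = np.asarray(accs)
        rows.append({
            "n_labels": n,
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std(ddof=0)) if repeats > 1 else 0.0,
            "repeats": repeats,
        })
    return pd.DataFrame(rows)


@dataclass
class QualityTrack:
    """Contiguous (start_s, end_s, grade) intervals covering the
    windowed span of a record; adjacent equal grades are merged."""

    intervals: list = field(default_factory=list)

    def lookup(self, t_s: float) -> int | None:
        """Grade at time t (half-open intervals); None outside the track."""
        for start, end, grade in self.intervals:
            if start <= t_s < end:
                return grade
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "grade"])

    @classmethod
    def from_windows(cls, windows_grades) -> "QualityTrack":
        """Build from an iterable of (start_s, end_s, grade), merging
        adjacent equal-grade intervals."""
        merged: list[list] = []
        for start, end, grade in sorted(windows_grades):
            if merged and merged[-1][2] == grade and abs(merged[-1][1] - start) < 1e-9:
                merged[-1][1] = end
            else:
                merged.append([start, end, grade])
        return cls(intervals=[tuple(iv) for iv in merged])


def build_quality_track(record: SignalRecord, model, thresholds: QualityThresholds | None = None):
    """Window, condition, featurize, score and classify one record.

    ``thresholds`` defaults to the calibration stored inside the model.
    Returns an empty track with a warning for records shorter than one
    window.
    """
    from .features import feature_vector
    from .preprocess import condition_record

    if thresholds is None:
        if not model.calibration:
            raise ValueError("model carries no calibration and no thresholds given")
        thresholds = QualityThresholds.from_dict(model.calibration)
    windows = condition_record(record)
    if not windows:
        warnings.warn(f"record {record.record_id!r} shorter than one window; empty track")
        return QualityTrack()
    X = np.vstack([feature_vector(w) for w in windows])
    flat = np.array([w.flags.get("flatline", False) for w in windows])
    grades = classify(model.score(X), thresholds, flatline=flat)
    return QualityTrack.from_windows(
        [(w.start_s, w.end_s, int(g)) for w, g in zip(windows, grades)]
    )
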