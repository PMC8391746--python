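"""Semisupervised mapping of anomaly scores to quality grades.

A small labeled validation set fixes two thresholds T1 <= T2 on the
anomaly-score axis: score < T1 is good, T1 <= score < T2 acceptable,
score >= T2 unacceptable.  The search is exhaustive over all
decision-equivalent threshold pairs (midpoints between adjacent sorted
unique scores, plus sentinels just outside the observed range) and
maximizes overall accuracy, with macro-F1, smallest T2 - T1, then
smallest T1 as deterministic tie-breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import ACCEPTABLE, GOOD, UNACCEPTABLE

__all__ = ["QualityThresholds", "classify", "find_thresholds", "subsample_labels"]


@dataclass
class QualityThresholds:
    """Ordered threshold pair with fit metadata."""

    t1: float
    t2: float
    n_labels: int = 0
    accuracy: float = float("nan")

    def __post_init__(self) -> None:
        if self.t1 > self.t2:
            raise ValueError("thresholds must satisfy T1 <= T2")

    def to_dict(self) -> dict:
        return {"t1": self.t1, "t2": self.t2,
                "n_labels": self.n_labels, "accuracy": self.accuracy}

    @classmethod
    def from_dict(cls, d: dict) -> "QualityThresholds":
        return cls(t1=d["t1"], t2=d["t2"],
                   n_labels=d.get("n_labels", 0), accuracy=d.get("accuracy", float("nan")))


def classify(scores, thresholds: QualityThresholds, flatline=None) -> np.ndarray:
    """Map anomaly scores to grades with the half-open [T1, T2) convention.

    ``flatline``: optional boolean mask; flagged windows are forced
    unacceptable regardless of score (full-window signal loss).
    """
    s = np.atleast_1d(np.asarray(scores, dtype=float))
    out = np.full(s.shape, GOOD, dtype=int)
    out[s >= thresholds.t1] = ACCEPTABLE
    out[s >= thresholds.t2] = UNACCEPTABLE
    if flatline is not None:
        out[np.atleast_1d(np.asarray(flatline, dtype=bool))] = UNACCEPTABLE
    return out if np.ndim(scores) else int(out[0])


def _macro_f1_from_counts(tp, true_n, pred_n) -> float:
    f1s = []
    for c in range(3):
        prec = tp[c] / pred_n[c] if pred_n[c] > 0 else 0.0
        rec = tp[c] / true_n[c] if true_n[c] > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(f1s))


def find_thresholds(scores, labels) -> QualityThresholds:
    """Exhaustive accuracy-maximizing search over candidate threshold pairs.

    Candidates are midpoints between adjacent sorted unique scores plus
    one sentinel just below the minimum and one just above the maximum,
    so every decision-equivalent partition of the labeled set is visited
    exactly once.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels) or len(scores) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        warnings.warn("all labels are one class; thresholds set at range extremes")

    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1e-9)
    cand = np.concatenate((
        [uniq[0] - 1e-3 * span],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1e-3 * span],
    ))
    k = len(cand)

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # pos[i]: number of scores strictly below cand[i]
    pos = np.searchsorted(s_sorted, cand, side="left")
    cum = np.zeros((3, k), dtype=int)
    for c in (GOOD, ACCEPTABLE, UNACCEPTABLE):
        cum[c] = np.concatenate(([0], np.cumsum(l_sorted == c)))[pos]
    n = len(labels)
    total_u = int(np.sum(labels == UNACCEPTABLE))

    # accuracy(i, j) = #good below T1 + #acceptable in [T1, T2) + #unacceptable >= T2
    gi = cum[GOOD][:, None]
    aj = cum[ACCEPTABLE][None, :]
    ai = cum[ACCEPTABLE][:, None]
    uj = cum[UNACCEPTABLE][None, :]
    correct = gi + (aj - ai) + (total_u - uj)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    correct = np.where(ii <= jj, correct, -1)

    best = int(correct.max())
    ties = np.argwhere(correct == best)
    if len(ties) > 1:
        scored = []
        for i, j in ties:
            t1, t2 = cand[i], cand[j]
            pred = np.full(n, GOOD, dtype=int)
            pred[scores >= t1] = ACCEPTABLE
            pred[scores >= t2] = UNACCEPTABLE
            tp = [np.sum((pred == c) & (labels == c)) for c in range(3)]
            true_n = [np.sum(labels == c) for c in range(3)]
            pred_n = [np.sum(pred == c) for c in range(3)]
            f1 = _macro_f1_from_counts(tp, true_n, pred_n)
            scored.append((-f1, t2 - t1, t1, i, j))
        scored.sort()
        _, _, _, i, j = scored[0]
    else:
        i, j = ties[0]
    return QualityThresholds(
        t1=float(cand[i]), t2=float(cand[j]),
        n_labels=n, accuracy=best / n,
    )


def subsample_labels(n_available: int, n: int, seed: int) -> np.ndarray:
    """Uniform without-replacement index subset, deterministic per seed."""
    if n > n_available:
        raise ValueError(f"cannot draw {n} labels from {n_available}")
    rng = np.random.default_rng(seed)
    return rng.choice(n_available, size=n, replace=False)
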