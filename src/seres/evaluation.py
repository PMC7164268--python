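"""Evaluation of support estimates against a true alignment.

The task annotates homologies *of the estimated alignment*, so homologies
that appear only in the true alignment are out of scope.  At a support
threshold t (a positive call is a score >= t):

* TP — estimated-alignment homologies that are in the true alignment and
  called positive;
* FP — estimated-alignment homologies not in the true alignment, called
  positive;
* FN — estimated-alignment homologies in the true alignment, called
  negative;
* TN — estimated-alignment homologies not in the true alignment, called
  negative.

Sweeping t yields ROC (false positive rate vs. true positive rate) and PR
(recall vs. precision) curves; ROC-AUC uses the trapezoid rule and PR-AUC a
right-step sum consistent with average precision.  Curves and AUCs depend
only on the score ordering, so any monotone rescaling of the support values
leaves them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from .io import MultipleAlignment, ResiduePair, extract_homologies
from .support import SupportAnnotation


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    @property
    def precision(self) -> float:
        # Convention: precision is 1.0 when nothing is called positive.
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0


def _labelled_scores(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
) -> tuple[np.ndarray, np.ndarray]:
    """(binary labels, score values) for every estimated-alignment homology."""
    true_pairs = extract_homologies(true_msa)
    est_pairs = extract_homologies(est_msa)
    labels = []
    values = []
    for pair in est_pairs:
        if pair not in scores.pair_scores:
            raise ValueError(f"no support score for estimated homology {pair}")
        labels.append(pair in true_pairs)
        values.append(scores.pair_scores[pair])
    return np.asarray(labels, dtype=bool), np.asarray(values, dtype=float)


def confusion_counts(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
    threshold: float,
) -> ConfusionCounts:
    """Confusion-matrix counts at one support threshold."""
    labels, values = _labelled_scores(true_msa, est_msa, scores)
    positive = values >= threshold
    return ConfusionCounts(
        tp=int(np.sum(labels & positive)),
        fp=int(np.sum(~labels & positive)),
        fn=int(np.sum(labels & ~positive)),
        tn=int(np.sum(~labels & ~positive)),
    )


def _sweep(
    labels: np.ndarray, values: np.ndarray
) -> list[tuple[float, ConfusionCounts]]:
    """Confusion counts at every distinct score threshold, descending, with
    a leading above-maximum threshold (nothing called positive)."""
    thresholds = [np.inf] + sorted(set(values.tolist()), reverse=True)
    out = []
    for t in thresholds:
        positive = values >= t
        out.append(
            (
                float(t),
                ConfusionCounts(
                    tp=int(np.sum(labels & positive)),
                    fp=int(np.sum(~labels & positive)),
                    fn=int(np.sum(labels & ~positive)),
                    tn=int(np.sum(~labels & ~positive)),
                ),
            )
        )
    return out


def roc_points(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the ROC curve, one per distinct support value
    plus the (0, 0) endpoint, in sweep order."""
    labels, values = _labelled_scores(true_msa, est_msa, scores)
    return roc_points_from_scores(labels, values)


def roc_points_from_scores(
    labels: Iterable[bool], values: Iterable[float]
) -> list[tuple[float, float]]:
    labels = np.asarray(list(labels), dtype=bool)
    values = np.asarray(list(values), dtype=float)
    if labels.all() or not labels.any():
        warnings.warn(
            "ROC curve is degenerate: only one class present", stacklevel=2
        )
    return [(c.fpr, c.tpr) for _, c in _sweep(labels, values)]


def pr_points(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
) -> list[tuple[float, float]]:
    """(recall, precision) points of the PR curve in sweep order; the first
    point has recall 0 and, by convention, precision 1."""
    labels, values = _labelled_scores(true_msa, est_msa, scores)
    return pr_points_from_scores(labels, values)


def pr_points_from_scores(
    labels: Iterable[bool], values: Iterable[float]
) -> list[tuple[float, float]]:
    labels = np.asarray(list(labels), dtype=bool)
    values = np.asarray(list(values), dtype=float)
    return [(c.tpr, c.precision) for _, c in _sweep(labels, values)]


def roc_auc_from_points(points: TypingSequence[tuple[float, float]]) -> float:
    """Trapezoid-rule area under an ROC point list (sweep order)."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def pr_auc_from_points(points: TypingSequence[tuple[float, float]]) -> float:
    """Right-step (average-precision-consistent) area under a PR curve."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    area = 0.0
    for (r0, _), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * p1
    return float(area)


def roc_auc(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
) -> float:
    return roc_auc_from_points(roc_points(true_msa, est_msa, scores))


def pr_auc(
    true_msa: MultipleAlignment,
    est_msa: MultipleAlignment,
    scores: SupportAnnotation,
) -> float:
    return pr_auc_from_points(pr_points(true_msa, est_msa, scores))


def aggregate_auc(
    datasets: TypingSequence[
        tuple[MultipleAlignment, MultipleAlignment, SupportAnnotation]
    ],
    curve: str = "roc",
    mode: str = "pooled",
) -> float:
    """AUC across several datasets.

    ``mode="pooled"`` concatenates all labelled homologies into one sweep
    (aggregate AUC); ``mode="mean"`` averages the per-dataset AUCs.
    """
    if curve not in ("roc", "pr"):
        raise ValueError(f"unknown curve {curve!r}")
    if mode == "mean":
        fn = roc_auc if curve == "roc" else pr_auc
        return float(np.mean([fn(t, e, s) for t, e, s in datasets]))
    if mode != "pooled":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    labels: list[bool] = []
    values: list[float] = []
    for t, e, s in datasets:
        lab, val = _labelled_scores(t, e, s)
        labels.extend(lab.tolist())
        values.extend(val.tolist())
    if curve == "roc":
        return roc_auc_from_points(roc_points_from_scores(labels, values))
    return pr_auc_from_points(pr_points_from_scores(labels, values))
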