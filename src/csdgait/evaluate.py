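"""Detection scoring: event matching, accuracy curves, ROC, cross-view grid.

The headline metric is event-level exact-frame accuracy: the fraction of
ground-truth toe-off events whose matched prediction lands on exactly
the right frame.  Its tolerance-relaxed generalisation is the
n-frame-error cumulative detection accuracy — the fraction of truth
events matched within ``d <= n`` frames — which is non-decreasing in n.
Misses count against accuracy (the denominator is always the number of
truth events); spurious extra predictions are reported separately as a
false-detection rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "DetectionResult",
    "MatchResult",
    "EvalReport",
    "match_events",
    "cumulative_accuracy",
    "roc",
    "evaluate_detections",
    "cross_view_matrix",
]


@dataclass
class DetectionResult:
    """Predicted toe-off frame indices plus the per-frame score trace."""

    predicted_indices: np.ndarray
    per_frame_scores: np.ndarray | None = None
    anchor_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted_indices = np.asarray(self.predicted_indices, dtype=np.int64)
        if self.predicted_indices.size > 1 and not np.all(
            np.diff(self.predicted_indices) > 0
        ):
            raise ValueError("predicted_indices must be strictly increasing")
        if self.per_frame_scores is not None:
            s = np.asarray(self.per_frame_scores, dtype=float)
            if s.size and (s.min() < 0 or s.max() > 1):
                raise ValueError("per-frame scores must lie in [0, 1]")
            self.per_frame_scores = s


@dataclass
class MatchResult:
    """One-to-one prediction/truth pairing within a frame tolerance.

    ``pairs`` holds ``(pred_index, truth_index, d)`` triples with signed
    ``d = pred - truth``; comparisons elsewhere use ``|d|``.
    """

    pairs: list[tuple[int, int, int]]
    unmatched_pred: list[int]
    unmatched_truth: list[int]
    max_d: int


def _event_array(events) -> np.ndarray:
    if isinstance(events, DetectionResult):
        return np.asarray(events.predicted_indices, dtype=np.int64)
    if hasattr(events, "toe_off_indices"):
        return np.asarray(events.toe_off_indices, dtype=np.int64)
    return np.asarray(events, dtype=np.int64)


def match_events(pred, truth, max_d: int = 12) -> MatchResult:
    """Optimally pair predicted with true events within ``max_d`` frames.

    Solves a one-to-one assignment that first maximises the number of
    pairs with ``|d| <= max_d`` and, among those, minimises the total
    ``|d|`` (linear sum assignment with a prohibitive cost on
    out-of-tolerance pairs).  Remaining predictions and truths are
    returned unmatched.  Inputs may be arrays of frame indices, a
    :class:`DetectionResult`, or a ground-truth object exposing
    ``toe_off_indices``.
    """
    p = _event_array(pred)
    t = _event_array(truth)
    if p.size == 0 or t.size == 0:
        return MatchResult(
            pairs=[],
            unmatched_pred=p.tolist(),
            unmatched_truth=t.tolist(),
            max_d=max_d,
        )
    d = p[:, None].astype(float) - t[None, :].astype(float)
    cost = np.abs(d)
    # any full set of valid pairs beats any solution wasting one on an
    # invalid pair, making the objective lexicographic
    big = (min(p.size, t.size) + 1) * (max_d + 1.0)
    cost = np.where(cost <= max_d, cost, big)
    rows, cols = linear_sum_assignment(cost)
    pairs, up, ut = [], set(range(p.size)), set(range(t.size))
    for i, j in zip(rows, cols):
        if abs(p[i] - t[j]) <= max_d:
            pairs.append((int(p[i]), int(t[j]), int(p[i] - t[j])))
            up.discard(i)
            ut.discard(j)
    pairs.sort(key=lambda x: x[1])
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[int(p[i]) for i in sorted(up)],
        unmatched_truth=[int(t[j]) for j in sorted(ut)],
        max_d=max_d,
    )


def cumulative_accuracy(
    pairs: Sequence[tuple[int, int, int]] | MatchResult,
    truth,
    tolerances: Sequence[int] | None = None,
) -> np.ndarray:
    """Cumulative detection accuracy at frame tolerances 0, 1, 2, ...

    The value at tolerance ``t`` is the fraction of ground-truth events
    whose matched prediction satisfies ``|d| <= t``; unmatched truths
    never count, so the curve is non-decreasing and bounded by 1.
    """
    if isinstance(pairs, MatchResult):
        pairs = pairs.pairs
    t_arr = _event_array(truth)
    if t_arr.size == 0:
        raise ValueError("cumulative accuracy undefined for empty ground truth")
    if tolerances is None:
        tolerances = range(0, 6)
    ds = np.array([abs(d) for _, _, d in pairs], dtype=float)
    return np.array([float((ds <= tol).sum()) / t_arr.size for tol in tolerances])


def roc(
    per_frame_scores: np.ndarray, per_frame_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR at every distinct threshold) and trapezoid AUC."""
    y = np.asarray(per_frame_labels).astype(int).ravel()
    s = np.asarray(per_frame_scores, dtype=float).ravel()
    if len(y) != len(s):
        raise ValueError("scores and labels length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present in the labels")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Aggregate detection scores for a collection of test sequences."""

    exact_accuracy: float
    tolerances: list[int]
    cumulative_curve: list[float]
    roc_fpr: list[float]
    roc_tpr: list[float]
    roc_auc: float
    n_truth: int
    n_pred: int
    false_detection_rate: float
    frame_accuracy: float
    matched_pairs: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exact_accuracy": self.exact_accuracy,
            "tolerances": list(self.tolerances),
            "cumulative_curve": list(map(float, self.cumulative_curve)),
            "roc_auc": self.roc_auc,
            "roc_fpr": list(map(float, self.roc_fpr)),
            "roc_tpr": list(map(float, self.roc_tpr)),
            "n_truth": self.n_truth,
            "n_pred": self.n_pred,
            "false_detection_rate": self.false_detection_rate,
            "frame_accuracy": self.frame_accuracy,
            "matched_pairs": [list(p) for p in self.matched_pairs],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_curves_csv(self, path: str | Path) -> None:
        lines = ["curve,x,y"]
        lines += [
            f"cumulative,{t},{v}" for t, v in zip(self.tolerances, self.cumulative_curve)
        ]
        lines += [f"roc,{f},{t}" for f, t in zip(self.roc_fpr, self.roc_tpr)]
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate_detections(
    detections: Sequence[DetectionResult],
    truths: Sequence,
    per_frame_scores: np.ndarray | None = None,
    per_frame_labels: np.ndarray | None = None,
    max_d: int = 12,
    max_tolerance: int = 5,
) -> EvalReport:
    """Score per-sequence detections against per-sequence ground truths.

    Event matching runs within each sequence; pairs are pooled before
    computing the exact accuracy and the cumulative curve.  If pooled
    per-frame scores/labels are given, a ROC is computed over them and a
    frame-level accuracy at threshold 0.5 is reported as well.
    """
    if len(detections) != len(truths):
        raise ValueError("detections and truths length mismatch")
    all_pairs: list[tuple[int, int, int]] = []
    n_truth = n_pred = n_false = 0
    for det, tru in zip(detections, truths):
        m = match_events(det, tru, max_d=max_d)
        all_pairs.extend(m.pairs)
        n_truth += _event_array(tru).size
        n_pred += _event_array(det).size
        n_false += len(m.unmatched_pred)
    if n_truth == 0:
        raise ValueError("no ground-truth events to evaluate")
    tolerances = list(range(0, max_tolerance + 1))
    ds = np.array([abs(d) for _, _, d in all_pairs], dtype=float)
    curve = [float((ds <= t).sum()) / n_truth for t in tolerances]
    if per_frame_scores is not None and per_frame_labels is not None:
        fpr, tpr, area = roc(per_frame_scores, per_frame_labels)
        frame_acc = float(
            (
                (np.asarray(per_frame_scores) >= 0.5).astype(int)
                == np.asarray(per_frame_labels).astype(int)
            ).mean()
        )
    else:
        fpr = tpr = np.array([])
        area = float("nan")
        frame_acc = float("nan")
    return EvalReport(
        exact_accuracy=curve[0],
        tolerances=tolerances,
        cumulative_curve=curve,
        roc_fpr=fpr.tolist(),
        roc_tpr=tpr.tolist(),
        roc_auc=area,
        n_truth=n_truth,
        n_pred=n_pred,
        false_detection_rate=n_false / n_pred if n_pred else 0.0,
        frame_accuracy=frame_acc,
        matched_pairs=all_pairs,
    )


def cross_view_matrix(
    models: Mapping[str, object],
    view_cases: Mapping[str, Sequence[tuple]],
    threshold: float = 0.5,
    min_separation: int = 6,
    max_d: int = 12,
) -> tuple[list[str], np.ndarray]:
    """Exact-frame event accuracy for every (train view, test view) pair.

    ``models`` maps a view tag to a fitted scorer (anything with the
    :meth:`~csdgait.cnn.ToeOffCNN.decision_scores` contract over stacked
    maps); ``view_cases`` maps a view tag to test cases, each a
    ``(maps, truth)`` pair of ordered normalized CSD-maps and a ground
    truth.  Cell (i, j) holds the accuracy of view-i's model on view-j's
    data.  Requires at least two views.
    """
    from .cnn import detect_events, predict_scores

    views = list(models)
    if len(views) < 2 or len(view_cases) < 2:
        raise ValueError("cross-view evaluation needs at least 2 views")
    if set(views) != set(view_cases):
        raise ValueError("models and view_cases must cover the same views")
    grid = np.zeros((len(views), len(views)))
    for i, train_view in enumerate(views):
        model = models[train_view]
        for j, test_view in enumerate(views):
            dets, truths = [], []
            for maps, truth in view_cases[test_view]:
                anchors, scores = predict_scores(model, maps)
                dets.append(
                    detect_events(
                        scores,
                        threshold=threshold,
                        min_separation=min_separation,
                        anchor_indices=anchors,
                    )
                )
                truths.append(truth)
            report = evaluate_detections(dets, truths, max_d=max_d)
            grid[i, j] = report.exact_accuracy
    return views, grid
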