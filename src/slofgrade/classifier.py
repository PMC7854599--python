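"""From raw regression scores to SLoF classifiers.

The scorer network emits one continuous number per image that tracks
fouling severity.  To act as a classifier it is thresholded twice — once
per binary task ("fouling": SLoF > 0, "heavy": SLoF = 2) — with the
thresholds read off the precision-recall curve of the combined out-of-fold
validation scores.  Three named policies are used: a high-precision
classifier at a 50% recall floor, a balanced classifier at 80% and a
high-recall classifier at 95%.

Model quality is summarised by mean average precision: the arithmetic mean
of the step-interpolated AP of the two binary tasks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import BinaryTask, BinomialEstimate, binarise
from .exceptions import ValidationError
from .synthetic import LabelSet, ScoreSet

__all__ = [
    "PRCurve",
    "ClassifierThresholds",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "select_threshold",
    "apply_thresholds",
    "evaluate_classifier",
    "read_scores_csv",
    "write_scores_csv",
    "read_thresholds_json",
    "write_thresholds_json",
]


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall per distinct score threshold, threshold-descending.

    A prediction is positive when score >= threshold, so recall is
    non-decreasing along the curve and reaches 1 at the minimum score.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    task: BinaryTask | None = None

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Score cutoffs for the two tasks, derived at one recall target."""

    fouling_threshold: float
    heavy_threshold: float
    recall_target: float

    def __post_init__(self) -> None:
        if not 0.0 < self.recall_target <= 1.0:
            raise ValidationError(
                f"recall_target must lie in (0, 1], got {self.recall_target}"
            )
        if self.heavy_threshold < self.fouling_threshold:
            warnings.warn(
                "heavy_threshold below fouling_threshold: the two task cutoffs "
                "are not monotone in the score; heavy takes precedence",
                stacklevel=2,
            )


def _aligned(scores: ScoreSet, truth: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    if set(scores.scores) != set(truth):
        missing = sorted(set(scores.scores) ^ set(truth))
        raise ValidationError(f"scores and truth cover different images: {missing[:10]}")
    ids = sorted(scores.scores)
    y = np.array([int(truth[i]) for i in ids])
    s = np.array([float(scores.scores[i]) for i in ids])
    if not set(np.unique(y)) <= {0, 1}:
        raise ValidationError("truth labels must be binary 0/1")
    return s, y


def pr_curve(
    scores: ScoreSet, truth: Mapping[str, int], task: BinaryTask | None = None
) -> PRCurve:
    """Precision-recall curve with one point per distinct score.

    ``truth`` maps image id to the binary task label.  Tied scores collapse
    to a single curve point; both classes must be present.
    """
    s, y = _aligned(scores, truth)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValidationError("pr_curve requires both a positive and a negative")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # last index of each tied block = counts at threshold == that score
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    thresholds = s_sorted[distinct]
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall, task=task)


def average_precision(scores: ScoreSet, truth: Mapping[str, int]) -> float:
    """Step-interpolated area under the precision-recall curve.

    AP = sum_i (R_i - R_{i-1}) * P_i over curve points in
    descending-threshold order with R_0 = 0.  No 11-point or trapezoidal
    smoothing.
    """
    curve = pr_curve(scores, truth)
    recall_prev = np.r_[0.0, curve.recall[:-1]]
    return float(np.sum((curve.recall - recall_prev) * curve.precision))


def mean_average_precision(scores: ScoreSet, slof_truth: LabelSet) -> float:
    """Mean of the fouling-task and heavy-task average precisions."""
    out = []
    for task in BinaryTask:
        truth = {iid: binarise(lab, task) for iid, lab in slof_truth.labels.items()}
        vals = set(truth.values())
        if vals != {0, 1}:
            raise ValidationError(
                f"task {task.value!r} is degenerate: only class(es) {sorted(vals)} present"
            )
        out.append(average_precision(scores, truth))
    return float(np.mean(out))


def select_threshold(curve: PRCurve, recall_target: float) -> float:
    """Precision-maximising threshold subject to a recall floor.

    Among curve points with recall >= recall_target, the most precise one
    is chosen; precision ties break towards the largest threshold.  Since
    the feasible set only grows as the recall floor drops, lowering the
    target can never lower the selected precision.
    """
    if not 0.0 < recall_target <= 1.0:
        raise ValidationError(f"recall_target must lie in (0, 1], got {recall_target}")
    idx = np.flatnonzero(curve.recall >= recall_target)
    assert idx.size > 0, "curve must reach the recall target at its minimum threshold"
    best = idx[np.argmax(curve.precision[idx])]  # argmax takes the earliest tie
    return float(curve.thresholds[best])


def apply_thresholds(scores: ScoreSet, th: ClassifierThresholds) -> LabelSet:
    """Map raw scores back to SLoF grades.

    SLoF 2 when score >= heavy_threshold, else SLoF 1 when
    score >= fouling_threshold, else SLoF 0.  Scores exactly at a cutoff
    take the higher class, and the heavy rule dominates if the two cutoffs
    cross.
    """
    if not (np.isfinite(th.fouling_threshold) and np.isfinite(th.heavy_threshold)):
        raise ValidationError("thresholds must be finite")
    labels = {}
    for iid, s in scores.scores.items():
        if s >= th.heavy_threshold:
            labels[iid] = 2
        elif s >= th.fouling_threshold:
            labels[iid] = 1
        else:
            labels[iid] = 0
    return LabelSet(rater_id=f"classifier_r{th.recall_target:g}", labels=labels)


@dataclass(frozen=True)
class ClassifierEvaluation:
    n_images: int
    confusion: np.ndarray  # rows = truth SLoF, columns = predicted SLoF
    precision: dict[BinaryTask, BinomialEstimate]
    recall: dict[BinaryTask, BinomialEstimate]


def evaluate_classifier(predicted: LabelSet, truth: LabelSet) -> ClassifierEvaluation:
    """Per-task precision/recall and the 3x3 SLoF confusion matrix."""
    if set(predicted.labels) != set(truth.labels):
        missing = sorted(set(predicted.labels) ^ set(truth.labels))
        raise ValidationError(f"predicted and truth cover different images: {missing[:10]}")
    ids = sorted(truth.labels)
    confusion = np.zeros((3, 3), dtype=int)
    for iid in ids:
        confusion[truth.labels[iid], predicted.labels[iid]] += 1

    precision = {}
    recall = {}
    for task in BinaryTask:
        t = np.array([binarise(truth.labels[i], task) for i in ids])
        c = np.array([binarise(predicted.labels[i], task) for i in ids])
        tp = int(np.sum(t & c))
        fp = int(np.sum(~t.astype(bool) & c.astype(bool)))
        fn = int(np.sum(t.astype(bool) & ~c.astype(bool)))
        precision[task] = BinomialEstimate(tp, tp + fp)
        recall[task] = BinomialEstimate(tp, tp + fn)
    return ClassifierEvaluation(
        n_images=len(ids), confusion=confusion, precision=precision, recall=recall
    )


# ---------------------------------------------------------------------------
# file interfaces

def write_scores_csv(score_sets: Sequence[ScoreSet], path: str | Path) -> None:
    """Scores CSV with columns image_id, fold, score."""
    rows = [
        {"image_id": iid, "fold": -1 if ss.fold is None else ss.fold, "score": s}
        for ss in score_sets
        for iid, s in sorted(ss.scores.items())
    ]
    pd.DataFrame(rows, columns=["image_id", "fold", "score"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_scores_csv(path: str | Path, provenance: str = "single_model") -> list[ScoreSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"image_id", "fold", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"scores table is missing columns {sorted(missing)}")
    out = []
    for fold, grp in df.groupby("fold", sort=True):
        out.append(
            ScoreSet(
                scores={str(r.image_id): float(r.score) for r in grp.itertuples()},
                provenance=provenance,
                fold=None if int(fold) < 0 else int(fold),
            )
        )
    return out


def write_thresholds_json(th: ClassifierThresholds, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fouling_threshold": th.fouling_threshold,
                "heavy_threshold": th.heavy_threshold,
                "recall_target": th.recall_target,
            },
            indent=2,
        )
        + "\n"
    )


def read_thresholds_json(path: str | Path) -> ClassifierThresholds:
    data = json.loads(Path(path).read_text())
    return ClassifierThresholds(
        fouling_threshold=float(data["fouling_threshold"]),
        heavy_threshold=float(data["heavy_threshold"]),
        recall_target=float(data["recall_target"]),
    )
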