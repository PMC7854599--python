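"""Expert-group pairing constructions and agreement statistics.

Because even experienced marine biologists disagree on patchy fouling, a
grader is benchmarked not against a single "true" label but against a
group of experts, via label pairs:

* within the group, each expert's label on each image is paired with each
  other expert's label, in both directions — with k raters over n images
  this yields n*k*(k-1) pairs (120 images x 3 experts -> 720 pairs);
* a candidate grader (another rater or a thresholded model) is paired with
  every group member's label on every image — n*k pairs (-> 360), with the
  group member always on the reference (truth) side.

Agreement, precision and recall are computed per binary task after
collapsing SLoF grades: "fouling" (SLoF > 0) and "heavy" (SLoF = 2).
Wilson score intervals accompany every proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .stats import wilson_ci
from .synthetic import LabelSet

__all__ = [
    "BinaryTask",
    "LabelPair",
    "BinomialEstimate",
    "AgreementResult",
    "binarise",
    "make_group_pairs",
    "make_rater_vs_group_pairs",
    "agreement_rate",
    "task_precision_recall",
    "cluster_bootstrap_agreement_ci",
    "summarise_pairs",
]


class BinaryTask(str, Enum):
    """The two binary collapses of the 3-class SLoF scale."""

    FOULING = "fouling"  # SLoF > 0: any macrofouling present
    HEAVY = "heavy"      # SLoF = 2: heavy fouling present


def binarise(label: int, task: BinaryTask) -> int:
    """Collapse a SLoF grade to the task's positive/negative indicator."""
    if label not in (0, 1, 2):
        raise ValidationError(f"label must be in {{0,1,2}}, got {label}")
    if task is BinaryTask.FOULING:
        return int(label > 0)
    return int(label == 2)


@dataclass(frozen=True)
class LabelPair:
    image_id: str
    reference: int
    candidate: int


@dataclass(frozen=True)
class BinomialEstimate:
    """A proportion with its Wilson interval; undefined on a 0 denominator."""

    successes: int
    trials: int

    @property
    def defined(self) -> bool:
        return self.trials > 0

    @property
    def estimate(self) -> float | None:
        return self.successes / self.trials if self.defined else None

    @property
    def ci(self) -> tuple[float, float] | None:
        return wilson_ci(self.successes, self.trials) if self.defined else None


@dataclass(frozen=True)
class AgreementResult:
    """Agreement plus per-task precision/recall for one set of label pairs."""

    n_pairs: int
    agreement: dict[BinaryTask, BinomialEstimate]
    precision: dict[BinaryTask, BinomialEstimate]
    recall: dict[BinaryTask, BinomialEstimate]


def _check_common_images(label_sets: Sequence[LabelSet]) -> list[str]:
    ids = sorted(label_sets[0].labels)
    reference = set(ids)
    for ls in label_sets[1:]:
        if set(ls.labels) != reference:
            missing = sorted(reference ^ set(ls.labels))
            raise ValidationError(
                f"label sets cover different images; mismatched ids: {missing[:10]}"
            )
    return ids


def make_group_pairs(label_sets: Sequence[LabelSet]) -> list[LabelPair]:
    """All ordered within-group pairs: n images x k raters x (k-1) partners."""
    if len(label_sets) < 2:
        raise ValidationError("group pairing requires at least two raters")
    ids = _check_common_images(label_sets)
    pairs = []
    for ref in label_sets:
        for cand in label_sets:
            if ref is cand:
                continue
            pairs.extend(
                LabelPair(iid, ref.labels[iid], cand.labels[iid]) for iid in ids
            )
    return pairs


def make_rater_vs_group_pairs(
    candidate: LabelSet, group: Sequence[LabelSet]
) -> list[LabelPair]:
    """Candidate vs every group rater on every image (group = truth side)."""
    if not group:
        raise ValidationError("group must contain at least one rater")
    ids = _check_common_images(list(group) + [candidate])
    return [
        LabelPair(iid, ref.labels[iid], candidate.labels[iid])
        for ref in group
        for iid in ids
    ]


def agreement_rate(
    pairs: Sequence[LabelPair], task: BinaryTask
) -> BinomialEstimate:
    """Proportion of pairs whose binarised labels coincide, with Wilson CI."""
    if not pairs:
        raise ValidationError("cannot compute agreement on an empty pair list")
    agree = sum(
        binarise(p.reference, task) == binarise(p.candidate, task) for p in pairs
    )
    return BinomialEstimate(agree, len(pairs))


def task_precision_recall(
    pairs: Sequence[LabelPair], task: BinaryTask
) -> tuple[BinomialEstimate, BinomialEstimate]:
    """Precision and recall of the candidate side against the reference side.

    The reference (truth) and candidate (prediction) labels are collapsed
    by the task rule; precision = TP/(TP+FP), recall = TP/(TP+FN).  A zero
    denominator yields an estimate flagged undefined rather than a silent
    zero.
    """
    if not pairs:
        raise ValidationError("cannot compute precision/recall on empty pairs")
    tp = fp = fn = 0
    for p in pairs:
        t = binarise(p.reference, task)
        c = binarise(p.candidate, task)
        tp += t & c
        fp += (1 - t) & c
        fn += t & (1 - c)
    return BinomialEstimate(tp, tp + fp), BinomialEstimate(tp, tp + fn)


def cluster_bootstrap_agreement_ci(
    pairs: Sequence[LabelPair],
    task: BinaryTask,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for agreement, resampling whole images.

    The pooled Wilson interval treats the several pairs built from one
    image as independent; this image-level (cluster) bootstrap is the
    cross-check that does not.
    """
    if not pairs:
        raise ValidationError("cannot bootstrap an empty pair list")
    by_image: dict[str, list[int]] = {}
    for p in pairs:
        by_image.setdefault(p.image_id, []).append(
            int(binarise(p.reference, task) == binarise(p.candidate, task))
        )
    images = sorted(by_image)
    agree = np.array([sum(by_image[i]) for i in images], dtype=float)
    counts = np.array([len(by_image[i]) for i in images], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(images), size=(n_boot, len(images)))
    stats = agree[idx].sum(axis=1) / counts[idx].sum(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def summarise_pairs(pairs: Sequence[LabelPair]) -> AgreementResult:
    """Agreement, precision and recall for both tasks on one pair set."""
    agreement = {task: agreement_rate(pairs, task) for task in BinaryTask}
    precision = {}
    recall = {}
    for task in BinaryTask:
        prec, rec = task_precision_recall(pairs, task)
        precision[task] = prec
        recall[task] = rec
    return AgreementResult(
        n_pairs=len(pairs), agreement=agreement, precision=precision, recall=recall
    )
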