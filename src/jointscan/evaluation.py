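"""Detection and classification evaluation.

Detection is judged per joint: predictions are matched one-to-one to
ground-truth joints greedily by descending IoU, and a joint counts as
*detected* when its matched IoU is strictly above 0.45.  Classification
(Tables of TP/FP/TN/FN per finding task) is computed over detected joints
only — an undetected joint is a detection failure, not a classification
false negative; detection rates and confusion counts are therefore
decoupled.

Metric arithmetic is the standard 2x2 kind: accuracy, precision, recall,
specificity and F-value per fold, then an unweighted mean across folds.
Ratios that are 0/0 on a fold are undefined and excluded from the
average.  Reported tables round half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .boxes import iou_matrix

__all__ = [
    "ConfusionCounts",
    "MetricSummary",
    "FoldSplit",
    "GTAssignment",
    "match_to_ground_truth",
    "detection_rate",
    "confusion",
    "metrics",
    "average_folds",
    "stratified_five_fold",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding used for reported tables (0.885 -> 0.89)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts for one finding task on one fold (detected joints only)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        """Ground-truth positives among detected joints (TP + FN)."""
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricSummary:
    """Per-fold (or fold-averaged) classification metrics; NaN = undefined."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f_value: float
    mean_iou: float = float("nan")

    def rounded(self, ndigits: int = 2) -> "MetricSummary":
        return MetricSummary(**{
            f.name: round_half_up(getattr(self, f.name), ndigits) for f in fields(self)
        })


@dataclass
class GTAssignment:
    """Greedy one-to-one matching of predictions to ground-truth joints."""

    pred_index: np.ndarray  # per-gt matched prediction index or -1
    iou: np.ndarray  # per-gt matched IoU (0 when unmatched)
    detected: np.ndarray  # per-gt bool: matched IoU strictly above threshold
    iou_success: float


def match_to_ground_truth(pred_boxes: np.ndarray, gt_boxes: np.ndarray,
                          iou_success: float = 0.45) -> GTAssignment:
    """Match predictions to ground truths greedily by descending IoU.

    ``pred_boxes`` (P,4) and ``gt_boxes`` (G,4) are center-form arrays.
    Each prediction and each ground truth participates in at most one
    match; a ground truth is detected iff its matched IoU > ``iou_success``.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=float).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    G, P = gt_boxes.shape[0], pred_boxes.shape[0]
    pred_index = np.full(G, -1, dtype=int)
    iou = np.zeros(G, dtype=float)
    if G and P:
        M = iou_matrix(pred_boxes, gt_boxes)  # (P, G)
        work = M.copy()
        for _ in range(min(P, G)):
            p, g = np.unravel_index(np.argmax(work), work.shape)
            if work[p, g] <= 0:
                break
            pred_index[g] = p
            iou[g] = M[p, g]
            work[p, :] = -1.0
            work[:, g] = -1.0
    detected = iou > iou_success
    return GTAssignment(pred_index, iou, detected, iou_success)


def detection_rate(n_detected: int, n_annotated: int) -> float:
    """Percentage of annotated joints detected (e.g. 899/900 -> 99.89)."""
    if n_annotated <= 0:
        raise ValueError("no annotated joints in the fold")
    return 100.0 * n_detected / n_annotated


def confusion(assignment: GTAssignment, pred_positive: Sequence[bool],
              gt_positive: Sequence[bool]) -> ConfusionCounts:
    """2x2 counts over detected joints for one finding task.

    ``pred_positive[g]`` is the predicted binary label for the prediction
    matched to ground-truth joint ``g`` (ignored when undetected);
    ``gt_positive[g]`` is the annotated flag.
    """
    pred_positive = np.asarray(pred_positive, dtype=bool)
    gt_positive = np.asarray(gt_positive, dtype=bool)
    det = assignment.detected
    tp = int(np.sum(det & gt_positive & pred_positive))
    fn = int(np.sum(det & gt_positive & ~pred_positive))
    fp = int(np.sum(det & ~gt_positive & pred_positive))
    tn = int(np.sum(det & ~gt_positive & ~pred_positive))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts, mean_iou: float = float("nan")) -> MetricSummary:
    """Standard 2x2 metrics; 0/0 ratios are NaN (undefined, excluded from means)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_value = float("nan")
    else:
        f_value = 2 * precision * recall / (precision + recall)
    return MetricSummary(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f_value=f_value,
        mean_iou=mean_iou,
    )


def average_folds(folds: Sequence[MetricSummary]) -> MetricSummary:
    """Unweighted arithmetic mean per metric; undefined fold values excluded."""
    if not folds:
        raise ValueError("no folds to average")

    def mean(name: str) -> float:
        vals = [getattr(f, name) for f in folds]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricSummary(**{f.name: mean(f.name) for f in fields(MetricSummary)})


@dataclass
class FoldSplit:
    """Five train/test partitions with finding-positive images balanced."""

    train_ids: list[list[int]]
    test_ids: list[list[int]]

    @property
    def n_folds(self) -> int:
        return len(self.test_ids)


def stratified_five_fold(dataset, seed: int = 0, n_folds: int = 5,
                         test_size: Optional[int] = None) -> FoldSplit:
    """Patient-level stratified cross-validation split.

    Patients (both their timepoints together, so no patient appears in a
    fold's train and test sets) are stratified by whether any of their
    joints carries a finding, shuffled deterministically, and dealt
    round-robin to ``n_folds`` groups.  Each fold's test set is trimmed to
    ``test_size`` images (default: the full group) and every remaining
    image trains, so with 260 images and test_size=50 each fold trains on
    210 images.
    """
    dataset = list(dataset)
    if len(dataset) < n_folds:
        raise ValueError(f"need at least {n_folds} images")
    rng = np.random.default_rng(seed)

    patients: dict = {}
    for idx, img in enumerate(dataset):
        patients.setdefault(img.patient_id, []).append(idx)

    def patient_positive(img_ids):
        return any(
            (j.has_ankylosis or bool(j.has_subluxation))
            for i in img_ids for j in dataset[i].joints
        )

    pos_patients = sorted(p for p, ids in patients.items() if patient_positive(ids))
    neg_patients = sorted(p for p in patients if p not in set(pos_patients))
    rng.shuffle(pos_patients)
    rng.shuffle(neg_patients)

    groups: list[list] = [[] for _ in range(n_folds)]
    for k, p in enumerate(pos_patients + neg_patients):
        groups[k % n_folds].append(p)

    test_ids, train_ids = [], []
    all_ids = set(range(len(dataset)))
    for g in groups:
        ids = [i for p in g for i in sorted(patients[p])]
        if test_size is not None and len(ids) > test_size:
            # drop whole patients from the end until the test set fits
            kept = []
            for p in g:
                pids = sorted(patients[p])
                if len(kept) + len(pids) <= test_size:
                    kept.extend(pids)
            ids = kept
        test_ids.append(sorted(ids))
        train_ids.append(sorted(all_ids - set(ids)))
    return FoldSplit(train_ids=train_ids, test_ids=test_ids)
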