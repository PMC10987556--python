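"""End-to-end prediction and fold evaluation.

Glues the stages together: per-detector tiled inference (scan ->
confidence filter -> NMS -> top-M), the two-detector ensemble merge, and
per-fold evaluation (detection rate, per-task confusion counts, metric
summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detector import CLASS_ABSENT, CLASS_PRESENT
from .ensemble import FusedDetection, ensemble
from .evaluation import (
    ConfusionCounts,
    GTAssignment,
    MetricSummary,
    confusion,
    detection_rate,
    match_to_ground_truth,
    metrics,
)
from .io import RunConfig
from .phantoms import AnnotatedImage
from .tiling import Detection, InferenceParams, plan_windows, predict_single

__all__ = ["predicted_positive", "predict_both", "FoldReport", "evaluate_fold",
           "per_window_recall"]


def predicted_positive(probs: Sequence[float]) -> bool:
    """Binary finding label of a box: present beats absent."""
    return probs[CLASS_PRESENT] > probs[CLASS_ABSENT]


def predict_both(image, det_ank, det_sub,
                 config: Optional[RunConfig] = None,
                 plan=None) -> list[FusedDetection]:
    """Run both detectors on one image and fuse their outputs.

    ``det_ank`` / ``det_sub`` are :class:`MultiboxDetector` instances or
    oracle callables ``(image, plan) -> [Detection]``.
    """
    config = config or RunConfig()
    if plan is None and isinstance(image, np.ndarray):
        plan = plan_windows(image.shape[1], image.shape[0],
                            config.window, config.stride)
    b1 = predict_single(image, det_ank,
                        InferenceParams(config.t_conf, config.t_iou1, config.m1), plan)
    b2 = predict_single(image, det_sub,
                        InferenceParams(config.t_conf, config.t_iou1, config.m2), plan)
    return ensemble(b1, b2, t_iou2=config.t_iou2, m1=config.m1)


def per_window_recall(detector, images: Sequence[AnnotatedImage], task: str,
                      t_conf: float = 0.5, t_iou1: float = 0.15,
                      top_m: int = 8, iou_success: float = 0.45) -> float:
    """Fraction of joints detected in a window centred on each joint.

    For every task joint a detector-sized window is cut around it, the
    window is predicted (decode -> confidence filter -> NMS -> top-M) and
    the joint counts as recalled when some surviving box overlaps it with
    IoU strictly above ``iou_success``.  The confidence threshold defaults
    to the recall-oriented 0.5 operating point rather than the deployment
    filter.
    """
    from .boxes import iou_matrix
    from .detector import extract_window
    from .tiling import filter_confidence, nms, predict_window, select_top_m

    win = detector.grid_config.window
    hits = total = 0
    for img in images:
        raster = img.intensity()
        for j in img.task_joints(task):
            ox = int(round(j.cx - win / 2))
            oy = int(round(j.cy - win / 2))
            window = extract_window(raster, ox, oy, win)
            dets = predict_window(detector, window)
            dets = select_top_m(nms(filter_confidence(dets, t_conf), t_iou1), top_m)
            target = np.array([j.cx - ox, j.cy - oy, j.w, j.h])
            if dets:
                boxes = np.array([d.box for d in dets])
                if iou_matrix(boxes, target[None]).max() > iou_success:
                    hits += 1
            total += 1
    return hits / total if total else float("nan")


@dataclass
class FoldReport:
    """Detection and classification results of one task on one fold."""

    task: str
    n_annotated: int
    n_detected: int
    counts: ConfusionCounts
    mean_iou: float

    @property
    def detection_rate(self) -> float:
        return detection_rate(self.n_detected, self.n_annotated)

    def metrics(self) -> MetricSummary:
        return metrics(self.counts, mean_iou=self.mean_iou)


def _labels_for(preds: Sequence, assignment: GTAssignment, task: str) -> np.ndarray:
    out = np.zeros(assignment.pred_index.shape[0], dtype=bool)
    for g, p in enumerate(assignment.pred_index):
        if p < 0:
            continue
        d = preds[p]
        probs = d.label_for(task) if isinstance(d, FusedDetection) else d.probs
        out[g] = predicted_positive(probs)
    return out


def evaluate_fold(images: Sequence[AnnotatedImage], preds_per_image: Sequence,
                  task: str, iou_success: float = 0.45) -> FoldReport:
    """Evaluate one task over a fold of images with their predictions.

    ``preds_per_image`` holds, per image, the fused ensemble output (or a
    single detector's :class:`Detection` list).  Detection uses greedy
    one-to-one IoU matching with success strictly above ``iou_success``;
    classification counts cover detected joints only.
    """
    tp = fp = tn = fn = 0
    n_annot = n_det = 0
    ious: list[float] = []
    for img, preds in zip(images, preds_per_image):
        gts = img.gt_boxes(task)
        gt_flags = img.gt_flags(task)
        n_annot += gts.shape[0]
        if gts.shape[0] == 0:
            continue
        boxes = (np.array([d.box for d in preds], dtype=float).reshape(-1, 4)
                 if preds else np.zeros((0, 4)))
        assignment = match_to_ground_truth(boxes, gts, iou_success)
        n_det += int(assignment.detected.sum())
        ious.extend(assignment.iou[assignment.detected].tolist())
        pred_flags = _labels_for(preds, assignment, task)
        c = confusion(assignment, pred_flags, gt_flags)
        tp += c.tp
        fp += c.fp
        tn += c.tn
        fn += c.fn
    return FoldReport(
        task=task,
        n_annotated=n_annot,
        n_detected=n_det,
        counts=ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        mean_iou=float(np.mean(ious)) if ious else float("nan"),
    )
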