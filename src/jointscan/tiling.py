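"""Whole-radiograph inference for one detector.

A detector sees fixed-size windows, so a full hand radiograph is scanned
on a regular grid of window origins (default 300-px windows shifted by
150 px; area beyond the image is zero-padded).  Per-window decoded boxes
are lifted into full-image coordinates, then duplicates from overlapping
windows are removed by confidence filtering (strict ``> t_conf``, default
0.9) and greedy NMS (inclusive ``>= t_iou``, default 0.15 — strict because
finger-joint boxes barely overlap in a hand film), and the top-M
candidates are kept (M=20 for the ankylosis task, 18 for
subluxation/dislocation, i.e. the number of target joints).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .boxes import decode_array, iou_matrix
from .detector import (
    CLASS_ABSENT,
    CLASS_PRESENT,
    MultiboxDetector,
    extract_window,
    softmax,
    to_model_input,
)

__all__ = [
    "Detection",
    "WindowPlan",
    "InferenceParams",
    "plan_windows",
    "scan_image",
    "predict_window",
    "filter_confidence",
    "nms",
    "select_top_m",
    "predict_from_raw",
    "predict_single",
    "detection_confidence",
]


@dataclass(frozen=True)
class Detection:
    """One predicted box in full-image coordinates with class probabilities."""

    box: tuple[float, float, float, float]  # (cx, cy, w, h)
    probs: tuple[float, float, float]  # background, present, absent
    confidence: float
    source: str = ""

    def box_array(self) -> np.ndarray:
        return np.asarray(self.box, dtype=float)


@dataclass(frozen=True)
class WindowPlan:
    """Regular grid of window origins covering an image with zero padding."""

    origins: tuple[tuple[int, int], ...]
    window: int
    stride: int
    padded_w: int
    padded_h: int

    def __len__(self) -> int:
        return len(self.origins)


@dataclass(frozen=True)
class InferenceParams:
    t_conf: float = 0.9
    t_iou1: float = 0.15
    top_m: int = 20


def detection_confidence(probs: np.ndarray) -> np.ndarray:
    """Confidence score: the larger of the two finding-class probabilities.

    Background probability is excluded so that boxes dominated by the
    background class cannot enter top-M selection.
    """
    probs = np.asarray(probs, dtype=float)
    return np.maximum(probs[..., CLASS_PRESENT], probs[..., CLASS_ABSENT])


def plan_windows(image_w: int, image_h: int, window: int = 300,
                 stride: int = 150) -> WindowPlan:
    """Window origins 0, stride, 2*stride, ... while the origin is inside the image."""
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image dimensions must be positive")
    if not (window >= stride > 0):
        raise ValueError("require window >= stride > 0")
    xs = list(range(0, image_w, stride))
    ys = list(range(0, image_h, stride))
    origins = tuple((ox, oy) for oy in ys for ox in xs)
    return WindowPlan(
        origins=origins,
        window=window,
        stride=stride,
        padded_w=xs[-1] + window,
        padded_h=ys[-1] + window,
    )


def predict_window(detector: MultiboxDetector, window: np.ndarray) -> list[Detection]:
    """Decode every default box of one grayscale window into detections."""
    logits, offsets = detector.forward(to_model_input(window))
    probs = softmax(logits)
    boxes = decode_array(offsets, detector.grid.boxes)
    conf = detection_confidence(probs)
    return [
        Detection(tuple(boxes[i]), tuple(probs[i]), float(conf[i]),
                  source=detector.task)
        for i in range(boxes.shape[0])
    ]


def scan_image(image: np.ndarray, detector: MultiboxDetector,
               plan: Optional[WindowPlan] = None,
               prefilter: float = 0.0) -> list[Detection]:
    """Scan a full image; per-window boxes are translated by the window origin.

    ``prefilter`` may drop obviously-background boxes early (confidence
    below the value); the default keeps everything.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    if plan is None:
        plan = plan_windows(W, H)
    out: list[Detection] = []
    for (ox, oy) in plan.origins:
        window = extract_window(image, ox, oy, plan.window)
        for det in predict_window(detector, window):
            if det.confidence < prefilter:
                continue
            cx, cy, w, h = det.box
            out.append(replace(det, box=(cx + ox, cy + oy, w, h)))
    return out


def filter_confidence(dets: Sequence[Detection], t_conf: float) -> list[Detection]:
    """Keep detections with confidence strictly above ``t_conf``; order preserved."""
    return [d for d in dets if d.confidence > t_conf]


def nms(dets: Sequence[Detection], t_iou: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending confidence (ties keep the earlier box
    in scan order); a box overlapping an already-kept box with IoU >=
    ``t_iou`` is removed.  The result is sorted by descending confidence.
    """
    dets = list(dets)
    if not dets:
        return []
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    boxes = np.array([dets[i].box for i in order], dtype=float)
    M = iou_matrix(boxes, boxes)
    keep: list[int] = []
    for r in range(len(order)):
        if all(M[r, k] < t_iou for k in keep):
            keep.append(r)
    return [dets[order[r]] for r in keep]


def select_top_m(dets: Sequence[Detection], m: int) -> list[Detection]:
    """The min(m, n) highest-confidence detections, descending, stable on ties."""
    if m < 0:
        raise ValueError("M must be nonnegative")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    return [dets[i] for i in order[:m]]


def predict_from_raw(raw: Sequence[Detection],
                     params: Optional[InferenceParams] = None) -> list[Detection]:
    """Confidence filter -> NMS -> top-M on an already-scanned detection list."""
    params = params or InferenceParams()
    dets = filter_confidence(raw, params.t_conf)
    dets = nms(dets, params.t_iou1)
    return select_top_m(dets, params.top_m)


def predict_single(image: np.ndarray, detector, params: Optional[InferenceParams] = None,
                   plan: Optional[WindowPlan] = None) -> list[Detection]:
    """Full single-detector pipeline: scan -> filter -> NMS -> top-M.

    ``detector`` is a :class:`MultiboxDetector`, or any callable
    ``(image, plan) -> list[Detection]`` producing raw full-image
    detections (e.g. the phantom oracle).
    """
    params = params or InferenceParams()
    if isinstance(detector, MultiboxDetector):
        raw = scan_image(image, detector, plan)
    else:
        raw = detector(image, plan)
    return predict_from_raw(raw, params)
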