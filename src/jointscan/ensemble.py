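"""Two-detector ensemble fusion of finger-joint detections.

The ankylosis detector and the subluxation/dislocation detector each emit
an independent box list (at most M1=20 and M2=18 boxes).  Cross-detector
pairs whose IoU reaches ``t_iou2`` (default 0.45) are assumed to be the
same joint and merge into a single box carrying both finding labels; a
box with no counterpart keeps its own label and receives the explicit
negative-class placeholder ``c_neg`` (probability 1 on the finding-absent
class) for the other task.  When (M1+1) or more candidates remain, the
list is cut to the M1 highest fused confidences — at least one detector
then proposed something that is not one of the target joints.

Matching is greedy one-to-one in descending combined confidence, so each
input box contributes to at most one fused output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import iou_matrix
from .tiling import Detection

__all__ = ["C_NEG", "FusedDetection", "fuse_pair", "ensemble"]

# explicit "no finding" label: all probability on the finding-absent class
C_NEG: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class FusedDetection:
    """One final joint candidate carrying both finding labels.

    ``label_ankylosis`` / ``label_subluxation`` are (background, present,
    absent) probability triples; a task whose detector proposed no
    overlapping box gets :data:`C_NEG`.  ``sources`` records which
    detectors contributed.
    """

    box: tuple[float, float, float, float]
    label_ankylosis: tuple[float, float, float]
    label_subluxation: tuple[float, float, float]
    confidence: float
    sources: tuple[str, ...]

    def label_for(self, task: str) -> tuple[float, float, float]:
        if task == "ankylosis":
            return self.label_ankylosis
        if task == "subluxation":
            return self.label_subluxation
        raise KeyError(f"unknown task {task!r}")


def fuse_pair(a: Detection, b: Detection, t_iou2: float = 0.45) -> FusedDetection:
    """Merge one ankylosis-detector box ``a`` with one subluxation box ``b``.

    Requires IoU(a, b) >= t_iou2.  Geometry and confidence follow the
    higher-confidence member (tie: the ankylosis box); each finding label
    comes from its own source detector.
    """
    iou_ab = float(iou_matrix(a.box_array()[None], b.box_array()[None])[0, 0])
    if iou_ab < t_iou2:
        raise ValueError(f"boxes overlap {iou_ab:.3f} < t_iou2={t_iou2}; not the same joint")
    winner = a if a.confidence >= b.confidence else b
    return FusedDetection(
        box=winner.box,
        label_ankylosis=a.probs,
        label_subluxation=b.probs,
        confidence=max(a.confidence, b.confidence),
        sources=("ankylosis", "subluxation"),
    )


def ensemble(b1: Sequence[Detection], b2: Sequence[Detection],
             t_iou2: float = 0.45, m1: int = 20) -> list[FusedDetection]:
    """Fuse the two detectors' outputs into the final dual-labelled joint list.

    ``b1`` is the ankylosis detector's output, ``b2`` the
    subluxation/dislocation detector's.  Returns at most ``m1`` fused
    detections sorted by descending confidence; the cut to ``m1`` applies
    only when m1+1 or more candidates remain.
    """
    b1 = list(b1)
    b2 = list(b2)
    fused: list[FusedDetection] = []
    used1 = np.zeros(len(b1), dtype=bool)
    used2 = np.zeros(len(b2), dtype=bool)

    if b1 and b2:
        M = iou_matrix(
            np.array([d.box for d in b1], dtype=float),
            np.array([d.box for d in b2], dtype=float),
        )
        pairs = [
            (i, j)
            for i in range(len(b1))
            for j in range(len(b2))
            if M[i, j] >= t_iou2
        ]
        # greedy one-to-one, descending combined confidence, deterministic ties
        pairs.sort(key=lambda ij: (-(b1[ij[0]].confidence + b2[ij[1]].confidence),
                                   ij[0], ij[1]))
        for i, j in pairs:
            if used1[i] or used2[j]:
                continue
            used1[i] = used2[j] = True
            fused.append(fuse_pair(b1[i], b2[j], t_iou2))

    singles: list[FusedDetection] = []
    for i, d in enumerate(b1):
        if not used1[i]:
            singles.append(FusedDetection(
                box=d.box, label_ankylosis=d.probs, label_subluxation=C_NEG,
                confidence=d.confidence, sources=("ankylosis",),
            ))
    for j, d in enumerate(b2):
        if not used2[j]:
            singles.append(FusedDetection(
                box=d.box, label_ankylosis=C_NEG, label_subluxation=d.probs,
                confidence=d.confidence, sources=("subluxation",),
            ))

    out = fused + singles
    order = sorted(range(len(out)), key=lambda k: (-out[k].confidence, k))
    out = [out[k] for k in order]
    if len(out) >= m1 + 1:
        out = out[:m1]
    return out
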