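"""Compact multibox joint detector: matching, losses, network, training.

One detector is trained per finding task (ankylosis, or pooled
subluxation/dislocation).  Each classifies its default boxes into three
classes — background (0), finding present (1), finding absent (2) — and
regresses center/size offsets against the default-box grid.

The training objective combines a localisation term (smooth-L1 on the
offsets of matched default boxes) and a confidence term (softmax
cross-entropy over matched boxes plus hard-mined negatives), normalised by
the number N of matched boxes::

    L = (1/N) * (L_conf + L_loc)

Negatives are mined at a 3:1 negative:positive ratio by descending
background cross-entropy, which keeps the overwhelmingly more frequent
background class from swamping the finding classes.

The network itself is a small numpy convolutional stack (conv3x3 + ReLU +
2x2 maxpool blocks) with per-feature-map classification and localisation
heads, sized for a 64x64 window by default; deeper variants for larger
power-of-two windows are built from the same config surface.  The
full-size 300-window six-feature-map *grid* is available from
:func:`jointscan.boxes.ssd300_grid_config` for box arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage

from .boxes import (
    DefaultBoxGrid,
    FeatureMapSpec,
    GridConfig,
    encode_array,
    iou_matrix,
    make_default_boxes,
    tiny_grid_config,
)
from .nnet import Adam, Conv2d, MaxPool2d, ReLU, Sequential

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_PRESENT",
    "CLASS_ABSENT",
    "MatchAssignment",
    "TrainConfig",
    "MultiboxDetector",
    "match_defaults",
    "smooth_l1",
    "localization_loss",
    "confidence_loss",
    "total_loss",
    "augment",
    "train_detector",
    "softmax",
]

CLASS_BACKGROUND = 0
CLASS_PRESENT = 1
CLASS_ABSENT = 2
N_CLASSES = 3


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchAssignment:
    """Assignment of default boxes to ground-truth boxes for one window.

    ``gt_index[i]`` is the matched ground-truth index for default box ``i``
    or -1; each matched default links to exactly one ground truth.  Every
    ground-truth box is guaranteed at least one matched default (its
    best-IoU default is force-matched), additional defaults join when
    their best IoU reaches the match threshold.
    """

    gt_index: np.ndarray
    gt_boxes: np.ndarray
    gt_labels: np.ndarray
    best_iou: Optional[np.ndarray] = None  # per-default max IoU over gts

    @property
    def pos(self) -> np.ndarray:
        return self.gt_index >= 0

    @property
    def neg(self) -> np.ndarray:
        return self.gt_index < 0

    def neg_pool(self, neg_iou_max: float = 1.0) -> np.ndarray:
        """Negatives eligible for hard mining.

        Unmatched defaults whose best ground-truth overlap is below
        ``neg_iou_max``; defaults in between are ignored (no gradient), so
        near-matches are not actively trained as background.
        """
        pool = self.neg
        if self.best_iou is not None and neg_iou_max < 1.0:
            pool = pool & (self.best_iou < neg_iou_max)
        return pool

    @property
    def n_matched(self) -> int:
        return int(self.pos.sum())


def match_defaults(
    gt_boxes: np.ndarray,
    grid: DefaultBoxGrid,
    match_iou: float = 0.5,
    gt_labels: Optional[np.ndarray] = None,
) -> MatchAssignment:
    """Match default boxes to ground truths (forced best match + IoU threshold).

    ``gt_boxes`` is (J,4) center form; ``gt_labels`` holds the per-joint
    finding flag (True = present).  Forced matches are assigned greedily in
    descending IoU over (default, ground-truth) pairs so that conflicts
    resolve deterministically in favour of the larger overlap.
    """
    if len(grid) == 0:
        raise ValueError("default box grid is empty")
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    J = gt_boxes.shape[0]
    if gt_labels is None:
        gt_labels = np.zeros(J, dtype=bool)
    gt_labels = np.asarray(gt_labels, dtype=bool)
    assign = np.full(len(grid), -1, dtype=int)
    if J == 0:
        return MatchAssignment(assign, gt_boxes, gt_labels,
                               best_iou=np.zeros(len(grid)))

    M = iou_matrix(grid.boxes, gt_boxes)  # (N, J)
    # forced best match, greedy by descending IoU, one default per gt
    work = M.copy()
    for _ in range(J):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        assign[i] = j
        work[i, :] = -1.0
        work[:, j] = -1.0
    # threshold matches for remaining defaults
    best_j = M.argmax(axis=1)
    best_iou = M[np.arange(len(grid)), best_j]
    extra = (assign < 0) & (best_iou >= match_iou)
    assign[extra] = best_j[extra]
    return MatchAssignment(assign, gt_boxes, gt_labels, best_iou=best_iou)


# ---------------------------------------------------------------------------
# losses


def smooth_l1(x):
    """Huber-style penalty: 0.5 x^2 for |x|<1, |x|-0.5 beyond."""
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    return out if out.ndim else float(out)


def _smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1.0, 1.0)


def localization_loss(
    assign: MatchAssignment, predicted_offsets: np.ndarray, encoded_targets: np.ndarray
) -> float:
    """Summed smooth-L1 over the four offsets of every matched default box."""
    predicted_offsets = np.asarray(predicted_offsets, dtype=float)
    encoded_targets = np.asarray(encoded_targets, dtype=float)
    if predicted_offsets.shape != encoded_targets.shape:
        raise ValueError(
            f"offset shape {predicted_offsets.shape} != target shape {encoded_targets.shape}"
        )
    if predicted_offsets.shape[0] != assign.gt_index.shape[0]:
        raise ValueError("offsets are not aligned with the default-box grid")
    pos = assign.pos
    if not pos.any():
        return 0.0
    diff = predicted_offsets[pos] - encoded_targets[pos]
    return float(smooth_l1(diff).sum())


def _select_negatives(assign: MatchAssignment, logits: np.ndarray,
                      neg_pos_ratio: int, neg_iou_max: float = 0.3) -> np.ndarray:
    """Indices of the hardest negatives (highest background cross-entropy).

    Unmatched defaults overlapping a ground truth at IoU >= ``neg_iou_max``
    are ignored rather than mined, so near-matches are not pushed toward
    the background class.
    """
    neg_idx = np.flatnonzero(assign.neg_pool(neg_iou_max))
    n_keep = min(neg_pos_ratio * assign.n_matched, neg_idx.size)
    if n_keep == 0:
        return neg_idx[:0]
    p = softmax(logits[neg_idx])
    ce = -np.log(np.clip(p[:, CLASS_BACKGROUND], 1e-12, None))
    order = np.argsort(-ce, kind="stable")
    return neg_idx[order[:n_keep]]


def _class_targets(assign: MatchAssignment) -> np.ndarray:
    """Per-default-box class target: present/absent for matched, background else."""
    tgt = np.full(assign.gt_index.shape[0], CLASS_BACKGROUND, dtype=int)
    pos = assign.pos
    lab = assign.gt_labels[assign.gt_index[pos]]
    tgt[pos] = np.where(lab, CLASS_PRESENT, CLASS_ABSENT)
    return tgt


def confidence_loss(assign: MatchAssignment, logits: np.ndarray,
                    neg_pos_ratio: int = 3, neg_iou_max: float = 0.3) -> float:
    """Softmax cross-entropy over matched boxes plus the hardest negatives."""
    logits = np.asarray(logits, dtype=float).reshape(-1, N_CLASSES)
    tgt = _class_targets(assign)
    pos_idx = np.flatnonzero(assign.pos)
    neg_idx = _select_negatives(assign, logits, neg_pos_ratio, neg_iou_max)
    counted = np.concatenate([pos_idx, neg_idx])
    if counted.size == 0:
        return 0.0
    p = softmax(logits[counted])
    ce = -np.log(np.clip(p[np.arange(counted.size), tgt[counted]], 1e-12, None))
    return float(ce.sum())


def total_loss(conf: float, loc: float, n_matched: int) -> float:
    """Combined objective (L_conf + L_loc) / N; zero when nothing matched."""
    if n_matched < 0:
        raise ValueError("n_matched must be nonnegative")
    if n_matched == 0:
        return 0.0
    return (conf + loc) / n_matched


def window_loss_and_grads(
    assign: MatchAssignment,
    logits: np.ndarray,
    offsets: np.ndarray,
    grid: DefaultBoxGrid,
    neg_pos_ratio: int = 3,
    neg_iou_max: float = 0.3,
):
    """Unnormalised (conf+loc, dlogits, doffsets, N) for one window.

    Gradients are of the *sum* (not yet divided by N); the caller divides
    by the batch-total N so the batch objective matches
    :func:`total_loss` applied to pooled sums.
    """
    logits = np.asarray(logits, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    dlogits = np.zeros_like(logits)
    doffsets = np.zeros_like(offsets)
    N = assign.n_matched
    if N == 0:
        return 0.0, 0.0, dlogits, doffsets, 0
    tgt = _class_targets(assign)
    pos_idx = np.flatnonzero(assign.pos)
    neg_idx = _select_negatives(assign, logits, neg_pos_ratio, neg_iou_max)
    counted = np.concatenate([pos_idx, neg_idx])
    p = softmax(logits[counted])
    ce = -np.log(np.clip(p[np.arange(counted.size), tgt[counted]], 1e-12, None))
    conf = float(ce.sum())
    grad = p.copy()
    grad[np.arange(counted.size), tgt[counted]] -= 1.0
    dlogits[counted] = grad

    enc = encode_array(assign.gt_boxes[assign.gt_index[pos_idx]], grid.boxes[pos_idx])
    diff = offsets[pos_idx] - enc
    loc = float(smooth_l1(diff).sum())
    doffsets[pos_idx] = _smooth_l1_grad(diff)
    return conf, loc, dlogits, doffsets, N


# ---------------------------------------------------------------------------
# the network


@dataclass
class TrainConfig:
    """Training hyperparameters (deployment-scale defaults).

    Adam with lr 0.001, betas (0.9, 0.999) and weight decay 0.0005;
    200 epochs at batch size 16; augmentation applied per transform with
    probability 0.5; default boxes match ground truths at IoU >= 0.5 with
    negatives mined 3:1.
    """

    epochs: int = 200
    batch_size: int = 16
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0005
    neg_pos_ratio: int = 3
    match_iou: float = 0.5
    neg_iou_max: float = 0.3  # defaults overlapping a gt above this are ignored
    augment_prob: float = 0.5


class MultiboxDetector:
    """A trainable multibox detector for one finding task.

    Backbone blocks are conv3x3 -> ReLU -> maxpool2; the feature maps named
    by ``taps`` (block indices) feed per-map classification and
    localisation heads whose outputs follow the default-box grid order.
    """

    def __init__(
        self,
        grid_config: Optional[GridConfig] = None,
        channels: Sequence[int] = (16, 32, 32, 48),
        taps: Sequence[int] = (2, 3),
        task: str = "ankylosis",
        seed: int = 0,
        dtype=np.float32,
    ):
        self.grid_config = grid_config or tiny_grid_config()
        self.grid = make_default_boxes(self.grid_config)
        self.channels = tuple(channels)
        self.taps = tuple(taps)
        self.task = task
        self.seed = int(seed)
        self.dtype = dtype
        self.epochs_trained = 0
        self.loss_history: list[float] = []
        self._build(np.random.default_rng(seed))

    def _build(self, rng: np.random.Generator) -> None:
        win = self.grid_config.window
        fms = self.grid_config.feature_maps
        if len(self.taps) != len(fms):
            raise ValueError("one tap per grid feature map is required")
        layers = []
        c_in = 3
        for c_out in self.channels:
            layers += [Conv2d(c_in, c_out, 3, rng=rng, dtype=self.dtype),
                       ReLU(), MaxPool2d(2)]
            c_in = c_out
        self.backbone = Sequential(layers)
        self._tap_act = {}
        self.cls_heads = []
        self.loc_heads = []
        for t, (block, fm) in enumerate(zip(self.taps, fms)):
            expect = win // (2 ** (block + 1))
            if fm.size != expect:
                raise ValueError(
                    f"feature map {t} size {fm.size} does not match tap block "
                    f"{block} resolution {expect} for window {win}"
                )
            act_idx = 3 * block + 2  # pool output of that block
            self._tap_act[t] = act_idx
            ch = self.channels[block]
            nb = fm.boxes_per_cell
            self.cls_heads.append(Conv2d(ch, nb * N_CLASSES, 3, rng=rng, dtype=self.dtype))
            self.loc_heads.append(Conv2d(ch, nb * 4, 3, rng=rng, dtype=self.dtype))

    # -- parameters -----------------------------------------------------
    def parameters(self):
        params = self.backbone.parameters()
        for h in self.cls_heads + self.loc_heads:
            params.extend(h.parameters())
        return params

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray):
        """Run a batch of windows; returns (logits (B,N,3), offsets (B,N,4)).

        A single window (3,H,W) is accepted and returns (N,3), (N,4).
        """
        single = x.ndim == 3
        if single:
            x = x[None]
        win = self.grid_config.window
        if x.shape[1:] != (3, win, win):
            raise ValueError(f"expected input (B,3,{win},{win}), got {x.shape}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self.backbone.forward(x)
        B = x.shape[0]
        logits_parts, offset_parts = [], []
        for t, fm in enumerate(self.grid_config.feature_maps):
            act = self.backbone.activations[self._tap_act[t]]
            nb, f = fm.boxes_per_cell, fm.size
            cls = self.cls_heads[t].forward(act)
            loc = self.loc_heads[t].forward(act)
            logits_parts.append(
                cls.reshape(B, nb, N_CLASSES, f, f).transpose(0, 3, 4, 1, 2)
                .reshape(B, f * f * nb, N_CLASSES)
            )
            offset_parts.append(
                loc.reshape(B, nb, 4, f, f).transpose(0, 3, 4, 1, 2)
                .reshape(B, f * f * nb, 4)
            )
        logits = np.concatenate(logits_parts, axis=1)
        offsets = np.concatenate(offset_parts, axis=1)
        if single:
            return logits[0], offsets[0]
        return logits, offsets

    def backward(self, dlogits: np.ndarray, doffsets: np.ndarray,
                 want_acts: Sequence[int] = ()):
        """Backpropagate output gradients; returns {'input': dx, act_idx: dA...}.

        ``want_acts`` lists backbone activation indices whose total incoming
        gradient should be reported (used by Grad-CAM).
        """
        if dlogits.ndim == 2:
            dlogits = dlogits[None]
            doffsets = doffsets[None]
        B = dlogits.shape[0]
        head_grads: dict[int, np.ndarray] = {}
        start = 0
        for t, fm in enumerate(self.grid_config.feature_maps):
            nb, f = fm.boxes_per_cell, fm.size
            n = f * f * nb
            dl = (dlogits[:, start:start + n].reshape(B, f, f, nb, N_CLASSES)
                  .transpose(0, 3, 4, 1, 2).reshape(B, nb * N_CLASSES, f, f))
            do = (doffsets[:, start:start + n].reshape(B, f, f, nb, 4)
                  .transpose(0, 3, 4, 1, 2).reshape(B, nb * 4, f, f))
            g = self.cls_heads[t].backward(np.ascontiguousarray(dl, dtype=self.dtype))
            g = g + self.loc_heads[t].backward(np.ascontiguousarray(do, dtype=self.dtype))
            idx = self._tap_act[t]
            head_grads[idx] = head_grads.get(idx, 0) + g
            start += n
        out: dict = {}
        layers = self.backbone.layers
        d = np.zeros_like(self.backbone.activations[-1])
        for i in range(len(layers) - 1, -1, -1):
            if i in head_grads:
                d = d + head_grads[i]
            if i in want_acts:
                out[i] = d.copy()
            d = layers[i].backward(d)
        out["input"] = d
        return out

    def activation(self, index: int) -> np.ndarray:
        """The recorded output of backbone layer ``index`` from the last forward."""
        return self.backbone.activations[index]

    @property
    def feature_layer_ids(self) -> dict[str, int]:
        """Named backbone activation indices usable for Grad-CAM (per block)."""
        return {f"block{b + 1}": 3 * b + 2 for b in range(len(self.channels))}

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights plus task/grid/seed metadata."""
        meta = {
            "task": self.task,
            "seed": self.seed,
            "epochs_trained": self.epochs_trained,
            "channels": list(self.channels),
            "taps": list(self.taps),
            "dtype": np.dtype(self.dtype).name,
            "loss_history": self.loss_history,
            "grid_config": {
                "window": self.grid_config.window,
                "feature_maps": [asdict(fm) for fm in self.grid_config.feature_maps],
            },
        }
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MultiboxDetector":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            fms = tuple(FeatureMapSpec(**fm) for fm in meta["grid_config"]["feature_maps"])
            det = cls(
                grid_config=GridConfig(window=meta["grid_config"]["window"], feature_maps=fms),
                channels=meta["channels"],
                taps=meta["taps"],
                task=meta["task"],
                seed=meta["seed"],
                dtype=np.dtype(meta["dtype"]),
            )
            det.epochs_trained = meta["epochs_trained"]
            det.loss_history = list(meta["loss_history"])
            for i, (p, _) in enumerate(det.parameters()):
                p[...] = z[f"p{i}"]
        return det


# ---------------------------------------------------------------------------
# augmentation


def augment(window: np.ndarray, boxes: np.ndarray, labels: np.ndarray,
            rng: np.random.Generator, prob: float = 0.5):
    """Stochastic training augmentation of one window and its annotations.

    Four transforms — intensity jitter, crop-resize, 90-degree rotation,
    horizontal flip — are each applied independently with probability
    ``prob``.  Boxes are transformed consistently; boxes whose center
    leaves the window during crop-resize are dropped.
    """
    window = np.asarray(window, dtype=float)
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    labels = np.asarray(labels).copy()
    H, W = window.shape

    if rng.random() < prob:  # intensity (brightness/contrast) jitter
        a = rng.uniform(0.8, 1.2)
        b = rng.uniform(-0.1, 0.1)
        window = np.clip(a * window + b, 0.0, 1.0)

    if rng.random() < prob:  # crop-resize (zoom in then scale back)
        z = rng.uniform(0.8, 1.0)
        s = max(2, int(round(z * min(H, W))))
        oy = int(rng.integers(0, H - s + 1))
        ox = int(rng.integers(0, W - s + 1))
        crop = window[oy:oy + s, ox:ox + s]
        fy, fx = H / s, W / s
        window = scipy.ndimage.zoom(crop, (fy, fx), order=1, mode="nearest")
        window = window[:H, :W]
        if boxes.size:
            boxes[:, 0] = (boxes[:, 0] - ox) * fx
            boxes[:, 1] = (boxes[:, 1] - oy) * fy
            boxes[:, 2] *= fx
            boxes[:, 3] *= fy
            keep = (boxes[:, 0] >= 0) & (boxes[:, 0] < W) & \
                   (boxes[:, 1] >= 0) & (boxes[:, 1] < H)
            boxes, labels = boxes[keep], labels[keep]

    if rng.random() < prob and H == W:  # multiple of 90 degrees
        k = int(rng.integers(1, 4))
        for _ in range(k):
            window = np.rot90(window, k=-1).copy()
            if boxes.size:
                cx = boxes[:, 0].copy()
                boxes[:, 0] = H - boxes[:, 1]
                boxes[:, 1] = cx
                boxes[:, [2, 3]] = boxes[:, [3, 2]]

    if rng.random() < prob:  # horizontal flip
        window = window[:, ::-1].copy()
        if boxes.size:
            boxes[:, 0] = W - boxes[:, 0]

    return window, boxes, labels


# ---------------------------------------------------------------------------
# training


def _task_joints(img, task: str):
    """Joint boxes and finding flags of one annotated image for a task."""
    boxes, flags = [], []
    for j in img.joints:
        flag = j.flag_for(task)
        if flag is None:
            continue
        boxes.append([j.cx, j.cy, j.w, j.h])
        flags.append(flag)
    return np.array(boxes, dtype=float).reshape(-1, 4), np.array(flags, dtype=bool)


def extract_window(raster: np.ndarray, ox: int, oy: int, size: int) -> np.ndarray:
    """Crop ``size`` x ``size`` at origin (ox, oy), zero-padding beyond the image."""
    H, W = raster.shape
    out = np.zeros((size, size), dtype=float)
    x1, y1 = max(ox, 0), max(oy, 0)
    x2, y2 = min(ox + size, W), min(oy + size, H)
    if x2 > x1 and y2 > y1:
        out[y1 - oy:y2 - oy, x1 - ox:x2 - ox] = raster[y1:y2, x1:x2]
    return out


def to_model_input(window: np.ndarray) -> np.ndarray:
    """Replicate a grayscale window into the 3-channel layout the model expects."""
    return np.repeat(window[None, :, :], 3, axis=0)


def _sample_crop(img, joint_box, win: int, rng: np.random.Generator):
    """Random window origin keeping ``joint_box`` fully inside the window."""
    x1 = joint_box[0] - joint_box[2] / 2.0
    x2 = joint_box[0] + joint_box[2] / 2.0
    y1 = joint_box[1] - joint_box[3] / 2.0
    y2 = joint_box[1] + joint_box[3] / 2.0
    lo_x, hi_x = int(np.ceil(x2 - win)), int(np.floor(x1))
    lo_y, hi_y = int(np.ceil(y2 - win)), int(np.floor(y1))
    ox = int(rng.integers(lo_x, max(lo_x, hi_x) + 1))
    oy = int(rng.integers(lo_y, max(lo_y, hi_y) + 1))
    return ox, oy


def _window_gts(boxes: np.ndarray, flags: np.ndarray, ox: int, oy: int, win: int):
    """Annotations whose center falls in the window, in window coordinates.

    Center-inclusion (rather than full containment) keeps joints that are
    partially cut by the window edge as positives, so their visible
    appearance is not trained as background.
    """
    if boxes.size == 0:
        return boxes.reshape(-1, 4), flags
    local = boxes.copy()
    local[:, 0] -= ox
    local[:, 1] -= oy
    inside = (
        (local[:, 0] >= 0) & (local[:, 0] < win)
        & (local[:, 1] >= 0) & (local[:, 1] < win)
    )
    return local[inside], flags[inside]


def train_detector(dataset, task: str, config: Optional[TrainConfig] = None,
                   seed: int = 0, detector: Optional[MultiboxDetector] = None,
                   log=None) -> MultiboxDetector:
    """Train a detector for one finding task on annotated images.

    Every epoch draws one random crop per task joint per image (so an
    epoch visits each annotated joint once), augments it, and optimises
    the combined loss with Adam.  Returns the trained detector with its
    per-epoch loss history.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    config = config or TrainConfig()
    det = detector or MultiboxDetector(task=task, seed=seed)
    win = det.grid_config.window
    rng = np.random.default_rng(seed)
    opt = Adam(det.parameters(), lr=config.lr, beta1=config.beta1,
               beta2=config.beta2, weight_decay=config.weight_decay)

    per_image = [_task_joints(img, task) for img in dataset]
    rasters = [np.asarray(img.intensity(), dtype=float) for img in dataset]

    for epoch in range(config.epochs):
        order = []
        for i, (boxes, _) in enumerate(per_image):
            order.extend((i, j) for j in range(boxes.shape[0]))
        rng.shuffle(order)
        batch_x, batch_assign = [], []
        epoch_losses = []

        def flush():
            if not batch_x:
                return
            x = np.stack(batch_x)
            logits, offsets = det.forward(x)
            conf_sum = loc_sum = 0.0
            N_total = 0
            dlog = np.zeros_like(logits)
            doff = np.zeros_like(offsets)
            for bi, assign in enumerate(batch_assign):
                c, l, dl, do, n = window_loss_and_grads(
                    assign, logits[bi], offsets[bi], det.grid,
                    config.neg_pos_ratio, config.neg_iou_max)
                conf_sum += c
                loc_sum += l
                N_total += n
                dlog[bi] = dl
                doff[bi] = do
            loss = total_loss(conf_sum, loc_sum, N_total)
            if N_total > 0:
                opt.zero_grad()
                det.backward(dlog / N_total, doff / N_total)
                opt.step()
            epoch_losses.append(loss)
            batch_x.clear()
            batch_assign.clear()

        for (i, j) in order:
            boxes, flags = per_image[i]
            ox, oy = _sample_crop(dataset[i], boxes[j], win, rng)
            window = extract_window(rasters[i], ox, oy, win)
            gts, gflags = _window_gts(boxes, flags, ox, oy, win)
            window, gts, gflags = augment(window, gts, gflags, rng,
                                          prob=config.augment_prob)
            assign = match_defaults(gts, det.grid, config.match_iou, gflags)
            batch_x.append(to_model_input(window))
            batch_assign.append(assign)
            if len(batch_x) == config.batch_size:
                flush()
        flush()
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else 0.0
        det.loss_history.append(mean_loss)
        det.epochs_trained += 1
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} loss {mean_loss:.4f}")
    return det
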