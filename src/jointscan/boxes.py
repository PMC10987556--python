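"""Axis-aligned box geometry for joint detection.

Boxes live in continuous pixel coordinates, origin at the top-left corner
of the image, x increasing rightward and y downward.  The canonical storage
form is center/size ``(cx, cy, w, h)``, matching the convention used for
joint annotations; corner form ``(x1, y1, x2, y2)`` is derived on demand.

This module also builds the deterministic grids of *default* (anchor)
boxes that a multibox detector regresses against, and the offset
encode/decode transform between a ground-truth box ``g`` and a default box
``d``::

    t_cx = (g.cx - d.cx) / d.w      t_w = log(g.w / d.w)
    t_cy = (g.cy - d.cy) / d.h      t_h = log(g.h / d.h)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Box",
    "OffsetTarget",
    "GridConfig",
    "FeatureMapSpec",
    "DefaultBoxGrid",
    "iou",
    "iou_matrix",
    "encode",
    "decode",
    "encode_array",
    "decode_array",
    "make_default_boxes",
    "ssd300_grid_config",
    "tiny_grid_config",
]


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive width or height."""


@dataclass(frozen=True)
class Box:
    """A rectangle stored as center coordinates plus side lengths, in pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "Box":
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)


@dataclass(frozen=True)
class OffsetTarget:
    """Dimensionless regression offsets of a box relative to a default box."""

    t_cx: float
    t_cy: float
    t_w: float
    t_h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.t_cx, self.t_cy, self.t_w, self.t_h], dtype=float)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint, 1 iff identical.

    Degenerate (zero-area) intersections contribute 0.
    """
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return float(min(inter / union, 1.0))


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two center-form box arrays of shape (N,4) and (M,4)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ax1 = a[:, 0] - a[:, 2] / 2.0
    ay1 = a[:, 1] - a[:, 3] / 2.0
    ax2 = a[:, 0] + a[:, 2] / 2.0
    ay2 = a[:, 1] + a[:, 3] / 2.0
    bx1 = b[:, 0] - b[:, 2] / 2.0
    by1 = b[:, 1] - b[:, 3] / 2.0
    bx2 = b[:, 0] + b[:, 2] / 2.0
    by2 = b[:, 1] + b[:, 3] / 2.0
    iw = np.minimum(ax2[:, None], bx2[None, :]) - np.maximum(ax1[:, None], bx1[None, :])
    ih = np.minimum(ay2[:, None], by2[None, :]) - np.maximum(ay1[:, None], by1[None, :])
    inter = np.clip(iw, 0.0, None) * np.clip(ih, 0.0, None)
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = (b[:, 2] * b[:, 3])[None, :]
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return np.clip(out, 0.0, 1.0)


def encode(g: Box, d: Box) -> OffsetTarget:
    """Offsets of ground-truth box ``g`` relative to default box ``d``."""
    if g.w <= 0 or g.h <= 0:
        raise InvalidBoxError("cannot encode a box with non-positive sides")
    return OffsetTarget(
        (g.cx - d.cx) / d.w,
        (g.cy - d.cy) / d.h,
        math.log(g.w / d.w),
        math.log(g.h / d.h),
    )


def decode(t: OffsetTarget, d: Box) -> Box:
    """Exact inverse of :func:`encode`: restore a box from offsets and its default."""
    return Box(
        t.t_cx * d.w + d.cx,
        t.t_cy * d.h + d.cy,
        math.exp(t.t_w) * d.w,
        math.exp(t.t_h) * d.h,
    )


def encode_array(g: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorised :func:`encode` over (N,4) center-form arrays."""
    g = np.asarray(g, dtype=float)
    d = np.asarray(d, dtype=float)
    out = np.empty_like(g)
    out[..., 0] = (g[..., 0] - d[..., 0]) / d[..., 2]
    out[..., 1] = (g[..., 1] - d[..., 1]) / d[..., 3]
    out[..., 2] = np.log(g[..., 2] / d[..., 2])
    out[..., 3] = np.log(g[..., 3] / d[..., 3])
    return out


def decode_array(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorised :func:`decode` over (N,4) arrays."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    out = np.empty_like(t)
    out[..., 0] = t[..., 0] * d[..., 2] + d[..., 0]
    out[..., 1] = t[..., 1] * d[..., 3] + d[..., 1]
    out[..., 2] = np.exp(t[..., 2]) * d[..., 2]
    out[..., 3] = np.exp(t[..., 3]) * d[..., 3]
    return out


@dataclass(frozen=True)
class FeatureMapSpec:
    """One detection feature map: resolution, box scale and per-cell shapes.

    ``scale`` is the box side as a fraction of the window side.  Each cell
    gets one box per aspect ratio plus, when ``extra_scale_box`` is set, an
    additional square box at scale ``sqrt(scale * next_scale)``.
    """

    size: int
    scale: float
    aspect_ratios: tuple[float, ...] = (1.0,)
    extra_scale_box: bool = False
    next_scale: float = 1.0

    @property
    def boxes_per_cell(self) -> int:
        return len(self.aspect_ratios) + (1 if self.extra_scale_box else 0)


@dataclass(frozen=True)
class GridConfig:
    window: int
    feature_maps: tuple[FeatureMapSpec, ...]

    @property
    def n_boxes(self) -> int:
        return sum(fm.size * fm.size * fm.boxes_per_cell for fm in self.feature_maps)


@dataclass
class DefaultBoxGrid:
    """Ordered default-box grid over one detector window.

    Ordering is deterministic: feature maps in config order, cells in
    row-major order (y outer, x inner), then per-cell boxes in aspect-ratio
    order with the extra-scale box last.  ``boxes`` is an (N,4) center-form
    array in window pixel coordinates; ``layer_index[i]`` names the feature
    map box ``i`` belongs to.
    """

    config: GridConfig
    boxes: np.ndarray = field(repr=False)
    layer_index: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.boxes.shape[0]


def make_default_boxes(config: GridConfig) -> DefaultBoxGrid:
    """Build the deterministic default-box grid for ``config``.

    Box centers sit at cell centers ``((i+0.5)/f) * window``; every center
    therefore lies inside the window extent.  Box sides may extend past the
    window (standard for anchor grids).
    """
    if not config.feature_maps:
        raise ValueError("grid config must list at least one feature map")
    rows = []
    layers = []
    win = float(config.window)
    for li, fm in enumerate(config.feature_maps):
        if fm.size <= 0:
            raise ValueError(f"feature map size must be positive, got {fm.size}")
        step = win / fm.size
        side = fm.scale * win
        cell_shapes = [
            (side * math.sqrt(ar), side / math.sqrt(ar)) for ar in fm.aspect_ratios
        ]
        if fm.extra_scale_box:
            extra = math.sqrt(fm.scale * fm.next_scale) * win
            cell_shapes.append((extra, extra))
        for iy in range(fm.size):
            cy = (iy + 0.5) * step
            for ix in range(fm.size):
                cx = (ix + 0.5) * step
                for (bw, bh) in cell_shapes:
                    rows.append((cx, cy, bw, bh))
                    layers.append(li)
    return DefaultBoxGrid(
        config=config,
        boxes=np.array(rows, dtype=float),
        layer_index=np.array(layers, dtype=int),
    )


def ssd300_grid_config() -> GridConfig:
    """The six-feature-map reference grid for a 300x300 window (8732 boxes).

    Scales follow the standard reference progression; per-cell counts are
    4, 6, 6, 6, 4, 4.
    """
    scales = [0.1, 0.2, 0.375, 0.55, 0.725, 0.9, 1.0]
    sizes = [38, 19, 10, 5, 3, 1]
    ar4 = (1.0, 2.0, 0.5)
    ar6 = (1.0, 2.0, 3.0, 0.5, 1.0 / 3.0)
    ars = [ar4, ar6, ar6, ar6, ar4, ar4]
    fms = tuple(
        FeatureMapSpec(
            size=sizes[k],
            scale=scales[k],
            aspect_ratios=ars[k],
            extra_scale_box=True,
            next_scale=scales[k + 1],
        )
        for k in range(6)
    )
    return GridConfig(window=300, feature_maps=fms)


def tiny_grid_config(window: int = 64) -> GridConfig:
    """Desk-scale two-feature-map grid for the compact detector (240 boxes at 64px)."""
    fms = (
        FeatureMapSpec(size=window // 8, scale=0.3, aspect_ratios=(1.0, 2.0, 0.5)),
        FeatureMapSpec(size=window // 16, scale=0.55, aspect_ratios=(1.0, 2.0, 0.5)),
    )
    return GridConfig(window=window, feature_maps=fms)
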