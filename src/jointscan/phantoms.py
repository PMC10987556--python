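"""Synthetic hand-radiograph phantoms with annotated finger joints.

Real hand films and their expert annotations cannot be redistributed, so
this module generates a desk-scale stand-in: two "hands" of five bright
finger columns on a dark background, each finger interrupted by two
darker gap bands (the distal PIP/IP joint and the proximal MP joint).
Per image that gives 20 annotated joints, 18 of which (excluding the
thumb IP) carry a subluxation/dislocation slot — the same annotation
arithmetic as the study data (260 images -> 5200 ankylosis-task and 4680
subluxation-task joints).

Finding appearance is deliberately minimal but learnable:

* ankylosis — the joint gap is filled at bone intensity (bony fusion,
  loss of the joint space);
* subluxation/dislocation — the segment distal to the joint is shifted
  laterally by ~45% of the finger width (loss of articular alignment).

Prevalences default to the study rates (157/5200 ankylosis, 60/4680
subluxation).  Findings are drawn once per patient-joint and shared by
the patient's two timepoints; the second film re-renders the same hand
with small geometric drift.  Rasters are stored as 10-bit intensities
(0..1023) to mirror the source data's 1024 gray levels.

An *oracle detector* emitting jittered ground truth stands in for a
trained network when testing the tiled-inference, ensemble and
evaluation stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .tiling import Detection, WindowPlan

__all__ = [
    "Joint",
    "AnnotatedImage",
    "PhantomParams",
    "generate_hand",
    "generate_dataset",
    "oracle_detector",
    "dataset_hash",
    "ANKYLOSIS_PREVALENCE",
    "SUBLUXATION_PREVALENCE",
]

ANKYLOSIS_PREVALENCE = 157 / 5200
SUBLUXATION_PREVALENCE = 60 / 4680

MAX_INTENSITY = 1023  # 10-bit gray levels


@dataclass(frozen=True)
class Joint:
    """One annotated joint box with its two finding flags.

    ``has_subluxation`` is ``None`` for the thumb IP joint, which carries
    no subluxation/dislocation annotation slot.
    """

    cx: float
    cy: float
    w: float
    h: float
    joint_type: str  # "PIP", "IP" or "MP"
    finger: int  # 0 = thumb .. 4 = little finger
    hand: str  # "L" or "R"
    has_ankylosis: bool
    has_subluxation: Optional[bool]

    def flag_for(self, task: str) -> Optional[bool]:
        if task == "ankylosis":
            return self.has_ankylosis
        if task == "subluxation":
            return self.has_subluxation
        raise KeyError(f"unknown task {task!r}")

    def box_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)


@dataclass
class AnnotatedImage:
    """An image raster plus its ground-truth joints.

    ``raster`` may be ``None`` for annotation-only records (e.g. read back
    from an annotation file whose pixels live in separate image files); in
    that case ``size`` supplies (height, width).
    """

    raster: Optional[np.ndarray]  # uint16, 0..1023
    joints: list[Joint]
    patient_id: str
    timepoint: int
    image_id: str = ""
    size: Optional[tuple[int, int]] = None
    file: Optional[str] = None

    @property
    def height(self) -> int:
        return self.raster.shape[0] if self.raster is not None else self.size[0]

    @property
    def width(self) -> int:
        return self.raster.shape[1] if self.raster is not None else self.size[1]

    def intensity(self) -> np.ndarray:
        """Raster as float in [0, 1]."""
        if self.raster is None:
            raise ValueError(f"image {self.image_id!r} has no pixel data loaded")
        return self.raster.astype(float) / MAX_INTENSITY

    def task_joints(self, task: str) -> list[Joint]:
        return [j for j in self.joints if j.flag_for(task) is not None]

    def gt_boxes(self, task: str) -> np.ndarray:
        return np.array([j.box_array() for j in self.task_joints(task)],
                        dtype=float).reshape(-1, 4)

    def gt_flags(self, task: str) -> np.ndarray:
        return np.array([bool(j.flag_for(task)) for j in self.task_joints(task)],
                        dtype=bool)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, appearance and prevalence settings for phantom generation.

    Lengths are fractions of the image extent unless stated; the default
    1005x835 raster mimics a 2010x1670 film after the 50% working resize.
    """

    image_w: int = 1005
    image_h: int = 835
    ankylosis_prevalence: float = ANKYLOSIS_PREVALENCE
    subluxation_prevalence: float = SUBLUXATION_PREVALENCE
    finger_width_frac: float = 0.5  # of the per-finger column spacing
    gap_frac: float = 0.35  # joint gap height as a fraction of finger width
    box_scale: float = 1.6  # joint box side as a multiple of finger width
    subluxation_shift: float = 0.45  # lateral offset, fraction of finger width
    bone_intensity: float = 0.75
    background_intensity: float = 0.08
    noise_sigma: float = 0.02

    def __post_init__(self):
        for p in (self.ankylosis_prevalence, self.subluxation_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")


def _sample_hand_geometry(params: PhantomParams, rng: np.random.Generator,
                          hand: str) -> list[dict]:
    """Per-finger layout for one hand: center x, width, top, base, joint depths."""
    W, H = params.image_w, params.image_h
    x0, x1 = (0.04 * W, 0.46 * W) if hand == "L" else (0.54 * W, 0.96 * W)
    sp = (x1 - x0) / 5.0
    fingers = []
    # relative finger heights: thumb short, middle tallest
    tops = [0.42, 0.22, 0.16, 0.20, 0.28]
    for f in range(5):
        fw = params.finger_width_frac * sp * rng.uniform(0.9, 1.1)
        if fw < 4.0:  # gap band would fall below one pixel
            raise ValueError(
                f"raster {W}x{H} too small: finger width {fw:.1f}px cannot "
                "render a joint gap"
            )
        cx = x0 + (f + 0.5) * sp + rng.uniform(-0.05, 0.05) * sp
        y_top = (tops[f] + rng.uniform(-0.02, 0.02)) * H
        y_base = (0.85 + rng.uniform(-0.02, 0.02)) * H
        span = y_base - y_top
        y_distal = y_top + (0.35 + rng.uniform(-0.03, 0.03)) * span
        y_mp = y_top + (0.70 + rng.uniform(-0.03, 0.03)) * span
        fingers.append(dict(cx=cx, fw=fw, y_top=y_top, y_base=y_base,
                            y_distal=y_distal, y_mp=y_mp))
    return fingers


def _draw_rect(img: np.ndarray, x1: float, y1: float, x2: float, y2: float,
               value: float) -> None:
    H, W = img.shape
    xi1, xi2 = max(int(round(x1)), 0), min(int(round(x2)), W)
    yi1, yi2 = max(int(round(y1)), 0), min(int(round(y2)), H)
    if xi2 > xi1 and yi2 > yi1:
        img[yi1:yi2, xi1:xi2] = value


def _render(params: PhantomParams, geometry: dict, flags: dict,
            rng: np.random.Generator) -> tuple[np.ndarray, list[Joint]]:
    W, H = params.image_w, params.image_h
    img = np.full((H, W), params.background_intensity, dtype=float)
    joints: list[Joint] = []
    for hand, fingers in geometry.items():
        for f, geo in enumerate(fingers):
            fw, cx = geo["fw"], geo["cx"]
            gh = params.gap_frac * fw
            bone = params.bone_intensity * rng.uniform(0.95, 1.05)
            yt, yd, ym, yb = geo["y_top"], geo["y_distal"], geo["y_mp"], geo["y_base"]
            ank_d, sub_d = flags[(hand, f, "distal")]
            ank_m, sub_m = flags[(hand, f, "mp")]
            shift = params.subluxation_shift * fw
            # lateral offsets of the three segments (distal, middle, proximal)
            dx1 = dx2 = 0.0
            if sub_m:
                s = rng.choice([-1.0, 1.0])
                dx1 += s * shift
                dx2 += s * shift
            if sub_d:
                dx1 += rng.choice([-1.0, 1.0]) * shift
            segs = [
                (cx + dx1, yt, yd - gh / 2),
                (cx + dx2, yd + gh / 2, ym - gh / 2),
                (cx, ym + gh / 2, yb),
            ]
            for (scx, sy1, sy2) in segs:
                _draw_rect(img, scx - fw / 2, sy1, scx + fw / 2, sy2, bone)
            if ank_d:  # bony fusion: joint space filled at bone intensity
                _draw_rect(img, cx + dx2 - fw / 2, yd - gh / 2,
                           cx + dx2 + fw / 2, yd + gh / 2, bone)
            if ank_m:
                _draw_rect(img, cx - fw / 2, ym - gh / 2, cx + fw / 2, ym + gh / 2, bone)

            side = params.box_scale * fw
            for (jy, jt, flag_key) in ((yd, "IP" if f == 0 else "PIP", "distal"),
                                       (ym, "MP", "mp")):
                ank, sub = flags[(hand, f, flag_key)]
                thumb_distal = (f == 0 and flag_key == "distal")
                joint = Joint(
                    cx=float(cx), cy=float(jy), w=float(side), h=float(side),
                    joint_type=jt, finger=f, hand=hand,
                    has_ankylosis=bool(ank),
                    has_subluxation=None if thumb_distal else bool(sub),
                )
                if not (side / 2 <= joint.cx <= W - side / 2
                        and side / 2 <= joint.cy <= H - side / 2):
                    raise ValueError(
                        f"raster {W}x{H} too small: joint box of side {side:.0f} "
                        f"at ({joint.cx:.0f},{joint.cy:.0f}) leaves the image"
                    )
                joints.append(joint)
    img += rng.normal(0.0, params.noise_sigma, img.shape)
    raster = np.clip(img, 0.0, 1.0)
    raster = np.round(raster * MAX_INTENSITY).astype(np.uint16)
    return raster, joints


def _sample_flags(params: PhantomParams, rng: np.random.Generator) -> dict:
    """Per-joint finding flags for one patient (shared across timepoints)."""
    flags = {}
    for hand in ("L", "R"):
        for f in range(5):
            for key in ("distal", "mp"):
                ank = rng.random() < params.ankylosis_prevalence
                thumb_distal = (f == 0 and key == "distal")
                sub = (not thumb_distal) and rng.random() < params.subluxation_prevalence
                flags[(hand, f, key)] = (ank, sub)
    return flags


def generate_hand(params: Optional[PhantomParams] = None, seed: int = 0,
                  patient_id: str = "P0000", timepoint: int = 1) -> AnnotatedImage:
    """Generate one annotated phantom deterministically from ``seed``."""
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    flags = _sample_flags(params, rng)
    geometry = {h: _sample_hand_geometry(params, rng, h) for h in ("L", "R")}
    raster, joints = _render(params, geometry, flags, rng)
    return AnnotatedImage(raster=raster, joints=joints, patient_id=patient_id,
                          timepoint=timepoint,
                          image_id=f"{patient_id}_t{timepoint}")


def _drift_geometry(geometry: dict, rng: np.random.Generator,
                    params: PhantomParams) -> dict:
    """Small positional drift between a patient's two films."""
    out = {}
    for hand, fingers in geometry.items():
        moved = []
        for geo in fingers:
            g = dict(geo)
            g["cx"] += rng.uniform(-0.05, 0.05) * geo["fw"]
            for key in ("y_top", "y_base", "y_distal", "y_mp"):
                g[key] += rng.uniform(-0.01, 0.01) * params.image_h
            moved.append(g)
        out[hand] = moved
    return out


def generate_dataset(n_images: int = 260, params: Optional[PhantomParams] = None,
                     seed: int = 0) -> list[AnnotatedImage]:
    """Generate ``n_images`` phantoms as pairs of films per patient.

    ``n_images`` must be even: each patient contributes two timepoints.
    Finding flags are drawn per patient-joint at the configured
    prevalences and shared by both films.
    """
    if n_images % 2:
        raise ValueError("n_images must be even (two films per patient)")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    dataset: list[AnnotatedImage] = []
    for p in range(n_images // 2):
        pid = f"P{p:04d}"
        flags = _sample_flags(params, rng)
        geometry = {h: _sample_hand_geometry(params, rng, h) for h in ("L", "R")}
        raster1, joints1 = _render(params, geometry, flags, rng)
        dataset.append(AnnotatedImage(raster1, joints1, pid, 1, f"{pid}_t1"))
        geometry2 = _drift_geometry(geometry, rng, params)
        raster2, joints2 = _render(params, geometry2, flags, rng)
        dataset.append(AnnotatedImage(raster2, joints2, pid, 2, f"{pid}_t2"))
    return dataset


def dataset_hash(dataset: Sequence[AnnotatedImage]) -> str:
    """SHA-256 over rasters and annotations; equal seeds give equal hashes."""
    h = hashlib.sha256()
    for img in dataset:
        h.update(img.raster.tobytes())
        h.update(img.patient_id.encode())
        h.update(str(img.timepoint).encode())
        for j in img.joints:
            h.update(repr((j.cx, j.cy, j.w, j.h, j.joint_type, j.finger, j.hand,
                           j.has_ankylosis, j.has_subluxation)).encode())
    return h.hexdigest()


def oracle_detector(
    img: AnnotatedImage,
    box_jitter: float = 0.0,
    conf_model: Optional[Callable[[np.random.Generator], float]] = None,
    dropout_rate: float = 0.0,
    seed: int = 0,
    task: str = "ankylosis",
    plan: Optional[WindowPlan] = None,
) -> list[Detection]:
    """A test double for a trained detector: perturbed ground-truth emissions.

    Each task joint is omitted with probability ``dropout_rate``;
    surviving joints emit their ground-truth box jittered by
    ``box_jitter`` (center shift and size rescale as a fraction of box
    size) with a confidence drawn from ``conf_model`` (default
    U(0.95, 0.999), above the deployment confidence threshold).  When a
    window ``plan`` is given, one jittered copy is emitted per window
    fully containing the joint, mimicking duplicate responses from
    overlapping windows.
    """
    if not (0.0 <= box_jitter < 1.0 and 0.0 <= dropout_rate <= 1.0):
        raise ValueError("jitter must be in [0,1), dropout in [0,1]")
    rng = np.random.default_rng(seed)
    conf_model = conf_model or (lambda r: float(r.uniform(0.95, 0.999)))
    out: list[Detection] = []
    for joint in img.task_joints(task):
        if rng.random() < dropout_rate:
            continue
        x1, y1 = joint.cx - joint.w / 2, joint.cy - joint.h / 2
        x2, y2 = joint.cx + joint.w / 2, joint.cy + joint.h / 2
        if plan is not None:
            emits = [
                (ox, oy) for (ox, oy) in plan.origins
                if ox <= x1 and oy <= y1 and x2 <= ox + plan.window and y2 <= oy + plan.window
            ] or [None]
        else:
            emits = [None]
        for _ in emits:
            cx = joint.cx + rng.uniform(-box_jitter, box_jitter) * joint.w
            cy = joint.cy + rng.uniform(-box_jitter, box_jitter) * joint.h
            w = joint.w * (1.0 + rng.uniform(-box_jitter, box_jitter))
            h = joint.h * (1.0 + rng.uniform(-box_jitter, box_jitter))
            conf = conf_model(rng)
            positive = bool(joint.flag_for(task))
            probs = np.empty(3)
            probs[1 if positive else 2] = conf
            probs[2 if positive else 1] = (1.0 - conf) * 0.8
            probs[0] = 1.0 - probs[1] - probs[2]
            out.append(Detection(box=(float(cx), float(cy), float(w), float(h)),
                                 probs=tuple(probs), confidence=conf, source=task))
    return out


def make_oracle(task: str, box_jitter: float = 0.0, dropout_rate: float = 0.0,
                seed: int = 0, conf_model=None):
    """Bind an oracle into the ``(image, plan) -> detections`` callable shape
    that :func:`jointscan.tiling.predict_single` accepts.

    The image argument must be the :class:`AnnotatedImage` itself (the
    oracle reads annotations, not pixels).
    """

    def run(img, plan):
        return oracle_detector(img, box_jitter=box_jitter, conf_model=conf_model,
                               dropout_rate=dropout_rate, seed=seed, task=task,
                               plan=plan)

    return run
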