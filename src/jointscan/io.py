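"""Annotation, image and configuration I/O.

Annotations travel as JSON: boxes are ``{"cx","cy","w","h"}`` in
*full-resolution* image pixels, with a top-level ``coordinate_scale``
recording the working resize (0.5 by default — processing happens on
half-size images), so working coordinates = stored * coordinate_scale.
Legacy corner-form boxes (``x1,y1,x2,y2``) are converted on read and
logged.

Images are grayscale PNG (16-bit) or DICOM; intensities are 10-bit
(1024 gray levels) and normalised as value/1023.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage
import yaml
from PIL import Image

from .phantoms import MAX_INTENSITY, AnnotatedImage, Joint

logger = logging.getLogger("jointscan")

__all__ = [
    "AnnotationError",
    "RunConfig",
    "write_annotations",
    "read_annotations",
    "load_image",
    "write_png",
    "write_dicom",
    "write_predictions",
    "read_predictions",
]


class AnnotationError(ValueError):
    """Raised when an annotation file violates the documented schema."""


FORMAT_NAME = "jointscan-annotations"
_JOINT_REQUIRED = ("joint_type", "finger", "hand", "has_ankylosis", "has_subluxation")


@dataclass
class RunConfig:
    """All pipeline thresholds and training hyperparameters.

    Defaults are the deployment operating point: confidence threshold
    0.9, single-detector NMS IoU 0.15, ensemble merge IoU 0.45, detection
    success IoU 0.45, M1=20 / M2=18 kept candidates, 300-px windows
    shifted by 150 px on half-size images, and Adam(0.001, 0.9, 0.999)
    with weight decay 0.0005 for 200 epochs at batch size 16.
    """

    t_conf: float = 0.9
    t_iou1: float = 0.15
    t_iou2: float = 0.45
    iou_success: float = 0.45
    m1: int = 20
    m2: int = 18
    window: int = 300
    stride: int = 150
    resize_factor: float = 0.5
    epochs: int = 200
    batch_size: int = 16
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0005
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise AnnotationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# annotations


def write_annotations(dataset: Sequence[AnnotatedImage], path,
                      coordinate_scale: float = 0.5) -> None:
    """Write dataset annotations; boxes are stored at full resolution."""
    images = []
    for img in dataset:
        joints = []
        for j in img.joints:
            joints.append({
                "cx": j.cx / coordinate_scale,
                "cy": j.cy / coordinate_scale,
                "w": j.w / coordinate_scale,
                "h": j.h / coordinate_scale,
                "joint_type": j.joint_type,
                "finger": j.finger,
                "hand": j.hand,
                "has_ankylosis": j.has_ankylosis,
                "has_subluxation": j.has_subluxation,
            })
        images.append({
            "image_id": img.image_id,
            "patient_id": img.patient_id,
            "timepoint": img.timepoint,
            # stored at full resolution, like the boxes
            "width": round(img.width / coordinate_scale),
            "height": round(img.height / coordinate_scale),
            "file": img.file,
            "joints": joints,
        })
    doc = {"format": FORMAT_NAME, "version": 1,
           "coordinate_scale": coordinate_scale, "images": images}
    Path(path).write_text(json.dumps(doc, indent=1))


def _parse_box(d: dict, scale: float, where: str) -> tuple[float, float, float, float]:
    if all(k in d for k in ("cx", "cy", "w", "h")):
        vals = (d["cx"], d["cy"], d["w"], d["h"])
    elif all(k in d for k in ("x1", "y1", "x2", "y2")):
        logger.info("converted legacy corner-format box in %s to center form", where)
        vals = ((d["x1"] + d["x2"]) / 2.0, (d["y1"] + d["y2"]) / 2.0,
                d["x2"] - d["x1"], d["y2"] - d["y1"])
    else:
        raise AnnotationError(f"{where}: box needs cx/cy/w/h (or legacy x1/y1/x2/y2)")
    return tuple(float(v) * scale for v in vals)


def read_annotations(path) -> list[AnnotatedImage]:
    """Read an annotation file back into annotation-only image records."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"not valid JSON: {e}") from e
    if doc.get("format") != FORMAT_NAME:
        raise AnnotationError(f"field 'format': expected {FORMAT_NAME!r}")
    scale = float(doc.get("coordinate_scale", 1.0))
    out = []
    for i, rec in enumerate(doc.get("images", [])):
        where = f"images[{i}]"
        for key in ("image_id", "patient_id", "timepoint", "width", "height", "joints"):
            if key not in rec:
                raise AnnotationError(f"{where}: missing field '{key}'")
        joints = []
        for k, jd in enumerate(rec["joints"]):
            jwhere = f"{where}.joints[{k}]"
            for key in _JOINT_REQUIRED:
                if key not in jd:
                    raise AnnotationError(f"{jwhere}: missing field '{key}'")
            cx, cy, w, h = _parse_box(jd, scale, jwhere)
            sub = jd["has_subluxation"]
            joints.append(Joint(
                cx=cx, cy=cy, w=w, h=h,
                joint_type=str(jd["joint_type"]), finger=int(jd["finger"]),
                hand=str(jd["hand"]), has_ankylosis=bool(jd["has_ankylosis"]),
                has_subluxation=None if sub is None else bool(sub),
            ))
        out.append(AnnotatedImage(
            raster=None, joints=joints, patient_id=str(rec["patient_id"]),
            timepoint=int(rec["timepoint"]), image_id=str(rec["image_id"]),
            size=(int(round(rec["height"] * scale)), int(round(rec["width"] * scale))),
            file=rec.get("file"),
        ))
    return out


# ---------------------------------------------------------------------------
# images


def write_png(raster: np.ndarray, path) -> None:
    """Write a 10-bit raster (0..1023) as a 16-bit grayscale PNG."""
    arr = np.asarray(raster)
    if arr.dtype != np.uint16:
        arr = np.clip(arr, 0, MAX_INTENSITY).astype(np.uint16)
    Image.fromarray(arr).save(path, format="PNG")


def write_dicom(raster: np.ndarray, path, patient_id: str = "ANON") -> None:
    """Write a raster as a minimal secondary-capture DICOM file."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    arr = np.asarray(raster)
    if arr.dtype != np.uint16:
        arr = np.clip(arr, 0, MAX_INTENSITY).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.Modality = "OT"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 10
    ds.HighBit = 9
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def load_image(path, resize_factor: Optional[float] = None) -> np.ndarray:
    """Load a grayscale PNG or DICOM raster, normalised to [0, 1].

    10-bit data maps 1023 -> 1.0 (8-bit PNGs map 255 -> 1.0).  When
    ``resize_factor`` is given the raster is rescaled bilinearly (0.5
    halves each side).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".dcm", ".dicom"):
            import pydicom
            ds = pydicom.dcmread(path)
            arr = ds.pixel_array.astype(float)
            bits = int(getattr(ds, "BitsStored", 10))
            maxv = float(2 ** bits - 1)
        else:
            with Image.open(path) as im:
                arr = np.array(im).astype(float)
            maxv = 255.0 if arr.max() <= 255 and arr.dtype != np.uint16 else float(MAX_INTENSITY)
            if arr.max() > MAX_INTENSITY:
                maxv = 65535.0
    except (OSError, ValueError) as e:
        raise IOError(f"cannot read image {path}: {e}") from e
    raster = arr / maxv
    if resize_factor is not None and resize_factor != 1.0:
        raster = scipy.ndimage.zoom(raster, resize_factor, order=1)
    return np.clip(raster, 0.0, 1.0)


# ---------------------------------------------------------------------------
# predictions


def _det_record(d) -> dict:
    rec = {
        "box": {"cx": d.box[0], "cy": d.box[1], "w": d.box[2], "h": d.box[3]},
        "confidence": d.confidence,
    }
    if hasattr(d, "probs"):  # single-detector output
        rec["probs"] = list(d.probs)
        rec["source"] = d.source
    else:  # fused output
        rec["label_ankylosis"] = list(d.label_ankylosis)
        rec["label_subluxation"] = list(d.label_subluxation)
        rec["sources"] = list(d.sources)
    return rec


def write_predictions(per_image: dict, path) -> None:
    """Write {image_id: [detections]} (single-detector or fused) as JSON."""
    doc = {
        "format": "jointscan-predictions",
        "images": {iid: [_det_record(d) for d in dets]
                   for iid, dets in per_image.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_predictions(path) -> dict:
    """Read predictions back as {image_id: [FusedDetection | Detection]}."""
    from .ensemble import FusedDetection
    from .tiling import Detection

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "jointscan-predictions":
        raise AnnotationError("field 'format': not a jointscan predictions file")
    out = {}
    for iid, recs in doc["images"].items():
        dets = []
        for r in recs:
            box = (r["box"]["cx"], r["box"]["cy"], r["box"]["w"], r["box"]["h"])
            if "probs" in r:
                dets.append(Detection(box=box, probs=tuple(r["probs"]),
                                      confidence=r["confidence"],
                                      source=r.get("source", "")))
            else:
                dets.append(FusedDetection(
                    box=box, label_ankylosis=tuple(r["label_ankylosis"]),
                    label_subluxation=tuple(r["label_subluxation"]),
                    confidence=r["confidence"], sources=tuple(r.get("sources", ())),
                ))
        out[iid] = dets
    return out
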