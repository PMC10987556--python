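"""Grad-CAM contribution maps for the joint detector.

For a chosen feature map A (channels k, pixels i,j) and target class c,
the channel weights are the spatial mean of the class-score gradient and
the map is the ReLU-rectified weighted channel sum::

    alpha_k = (1/Z) * sum_ij  d y_c / d A_k[i,j]
    G_c     = ReLU( sum_k alpha_k * A_k )

Gradients of classes other than the target are zeroed before
backpropagation.  For a multibox detector the class score ``y_c`` is
defined here as the summed class-c logit over the boxes surviving the
confidence filter (falling back to the single most confident box when
none passes) — a detector emits many box scores, not one, so some
reduction must be chosen; this one weights exactly the boxes that drive
the final prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .detector import MultiboxDetector, softmax
from .tiling import detection_confidence

__all__ = ["HeatMap", "gradcam_from_arrays", "gradcam"]


@dataclass
class HeatMap:
    """Nonnegative per-pixel contribution map from one layer for one class."""

    values: np.ndarray  # (H, W), >= 0
    alpha: np.ndarray  # per-channel weights
    layer: str
    class_index: int

    def upsampled(self, height: int, width: int) -> np.ndarray:
        """Bilinear upsampling for overlay rendering; the raw map is kept."""
        h, w = self.values.shape
        return scipy.ndimage.zoom(self.values, (height / h, width / w), order=1)


def gradcam_from_arrays(activations: np.ndarray, gradients: np.ndarray,
                        layer: str = "", class_index: int = 0) -> HeatMap:
    """Grad-CAM from an explicit feature map and its class-score gradient.

    ``activations`` and ``gradients`` are (K, H, W): the feature map A and
    d y_c / d A.
    """
    A = np.asarray(activations, dtype=float)
    dA = np.asarray(gradients, dtype=float)
    if A.shape != dA.shape:
        raise ValueError(f"activation shape {A.shape} != gradient shape {dA.shape}")
    if A.ndim != 3:
        raise ValueError("expected (channels, H, W) arrays")
    alpha = dA.mean(axis=(1, 2))
    g = np.einsum("k,kij->ij", alpha, A)
    return HeatMap(values=np.maximum(g, 0.0), alpha=alpha, layer=layer,
                   class_index=class_index)


def gradcam(detector: MultiboxDetector, window: np.ndarray, layer_id: str,
            class_index: int, t_conf: float = 0.9) -> HeatMap:
    """Grad-CAM for one detector window at a named backbone feature map.

    ``layer_id`` is one of ``detector.feature_layer_ids`` (e.g.
    ``"block3"``); ``class_index`` is 0 background, 1 finding-present,
    2 finding-absent.  ``window`` is a 3-channel model input
    (3, win, win) or a grayscale (win, win) raster.
    """
    layer_ids = detector.feature_layer_ids
    if layer_id not in layer_ids:
        raise KeyError(f"unknown layer {layer_id!r}; choose from {sorted(layer_ids)}")
    if not 0 <= class_index < 3:
        raise ValueError("class index must be 0, 1 or 2")
    window = np.asarray(window, dtype=float)
    if window.ndim == 2:
        window = np.repeat(window[None], 3, axis=0)
    logits, _ = detector.forward(window)

    probs = softmax(logits)
    conf = detection_confidence(probs)
    selected = conf > t_conf
    if not selected.any():
        selected = conf == conf.max()

    # y_c = sum of the class-c logit over the selected boxes; all other
    # class gradients are zeroed
    dlogits = np.zeros_like(logits)
    dlogits[selected, class_index] = 1.0
    doffsets = np.zeros(logits.shape[:1] + (4,), dtype=logits.dtype)
    act_idx = layer_ids[layer_id]
    grads = detector.backward(dlogits, doffsets, want_acts=(act_idx,))
    A = detector.activation(act_idx)[0]
    dA = grads[act_idx][0]
    return gradcam_from_arrays(A, dA, layer=layer_id, class_index=class_index)
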