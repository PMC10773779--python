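"""Grad-CAM saliency over the image branch, and a lesion-localization
score against ground-truth masks.

The class score used for gradients is the pre-softmax logit of the
target class (softmax gradients vanish at saturation).  Channel weights
are the spatial means of the score gradient at the target layer; the map
is the rectified weighted sum of activations, bilinearly upsampled to
input size and min-max normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .model import PrognosisModel
from .nn import Tensor

__all__ = ["SaliencyMap", "grad_cam", "localization_score"]


@dataclass
class SaliencyMap:
    values: np.ndarray            # (H, W) in [0, 1]
    target_layer: str
    target_class: int
    constant: bool = False        # raw map was constant -> all zeros


def grad_cam(model: PrognosisModel, image: np.ndarray,
             metadata: np.ndarray | None = None, target_class: int = 1,
             target_layer: str | None = None) -> SaliencyMap:
    """Saliency of `target_class`'s logit w.r.t. one image.

    ``image`` is (H, W) or (3, H, W); ``target_layer`` defaults to the
    deepest joint feature of the image branch.
    """
    valid = model.image_branch.layer_names()
    if target_layer is None:
        target_layer = valid[-1]
    if target_layer not in valid:
        raise ValueError(
            f"unknown target layer {target_layer!r}; valid layers: {valid}")

    if image.ndim == 2:
        image = np.repeat(image[None], 3, axis=0)
    h_in, w_in = image.shape[-2:]
    model.eval()
    x = Tensor(image[None])
    meta = Tensor(metadata[None]) if metadata is not None else None
    logits = model(x, meta)
    logits[0, target_class].backward()

    act = model.image_branch.activations[target_layer]
    a = act.data[0]                              # (C, h, w)
    g = act.grad[0]
    weights = g.mean(axis=(1, 2))                # (C,)
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    cam = zoom(cam, (h_in / cam.shape[0], w_in / cam.shape[1]), order=1)
    cam = np.clip(cam, 0.0, None)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return SaliencyMap(np.zeros((h_in, w_in)), target_layer,
                           target_class, constant=True)
    return SaliencyMap((cam - lo) / (hi - lo), target_layer, target_class)


def localization_score(saliency: SaliencyMap | np.ndarray,
                       mask: np.ndarray) -> float:
    """Mean saliency inside the lesion mask divided by mean saliency
    outside; > 1 indicates lesion-concentrated attention."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else saliency
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise ValueError("saliency and mask shapes differ")
    if not mask.any():
        raise ValueError("lesion mask is empty")
    inside = float(values[mask].mean())
    outside_px = values[~mask]
    outside = float(outside_px.mean()) if outside_px.size else 0.0
    if outside == 0.0:
        return math.inf if inside > 0 else 1.0
    return inside / outside
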