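"""Grad-CAM heatmaps over the last convolutional stage.

Channel weights are the spatial average of the target-class logit's
gradient with respect to each feature map of the chosen layer; the
heatmap is the rectified weighted sum of those maps, bilinearly upsampled
to 224x224 and min-max scaled to [0,1] (an all-zero map is returned as-is
with a warning rather than divided by zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from . import nn
from .classifier import Backbone, InvalidModelError
from .patches import PATCH_SIZE, PatchRecord

CLASS_INDEX = {"low": 0, "high": 1}


@dataclass
class Heatmap:
    values: np.ndarray     # (h, w) non-negative, last-conv spatial grid
    upsampled: np.ndarray  # (224, 224) in [0, 1]
    target_class: str


def _resolve(model, layer_index):
    if isinstance(model, Backbone):
        return model.net, (model.last_block_index if layer_index is None else layer_index)
    if isinstance(model, nn.Sequential):
        if layer_index is None:
            convs = [i for i, m in enumerate(model.layers)
                     if isinstance(m, (nn.Conv2d, nn.BasicBlock))]
            if not convs:
                raise InvalidModelError("model has no convolutional stage")
            layer_index = convs[-1]
        return model, layer_index
    raise InvalidModelError(f"cannot run Grad-CAM on {type(model).__name__}")


def gradcam(model, patch: np.ndarray, target_class: str = "high",
            layer_index: int | None = None) -> Heatmap:
    """Compute a Grad-CAM heatmap for one normalized patch (3,H,W)."""
    net, idx = _resolve(model, layer_index)
    if not any(isinstance(m, (nn.Conv2d, nn.BasicBlock)) for m in net.layers):
        raise InvalidModelError("model has no convolutional stage")
    x = np.asarray(patch, dtype=nn.F32)[None]
    act = net.forward_upto(x, idx, train=False)           # (1, C, h, w)
    logits = net.forward_from(act, idx, train=False)      # (1, n_classes)
    onehot = np.zeros_like(logits)
    onehot[0, CLASS_INDEX[target_class]] = 1.0
    dact = net.backward_downto(onehot, idx)               # d logit / d act
    alpha = dact[0].mean(axis=(1, 2))                     # (C,) channel weights
    cam = np.maximum((alpha[:, None, None] * act[0]).sum(axis=0), 0.0)
    if cam.max() > 0:
        up = resize(cam, (PATCH_SIZE, PATCH_SIZE), order=1, mode="edge",
                    anti_aliasing=False)
        up = up / up.max()
    else:
        warnings.warn("all-zero Grad-CAM heatmap; returning it unscaled")
        up = np.zeros((PATCH_SIZE, PATCH_SIZE))
    return Heatmap(values=cam, upsampled=np.clip(up, 0.0, 1.0),
                   target_class=target_class)


def overlay(heatmap: Heatmap, patch: PatchRecord | np.ndarray,
            alpha: float = 0.4, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the colormapped heatmap onto the patch (224x224x3 uint8)."""
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0,1]")
    px = patch.pixels if isinstance(patch, PatchRecord) else np.asarray(patch)
    colored = colormaps[cmap](heatmap.upsampled)[:, :, :3] * 255.0
    blended = (1 - alpha) * px.astype(np.float64) + alpha * colored
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
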