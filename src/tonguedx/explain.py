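"""Grad-CAM heatmaps for the deep backbone and lesion-localization scoring.

Grad-CAM weights the activations of a convolutional layer by the
spatially-pooled gradient of a class logit with respect to that layer,
rectifies the weighted sum, upsamples it bilinearly to the input size, and
min-max normalizes to [0, 1] (an all-zero map stays all-zero).

Because the synthetic cohort records ground-truth lesion sub-masks (cracks,
tooth marks, yellow coating, red tip), heatmap quality is quantifiable: the
localization score is the ratio of mean heat inside a lesion mask to mean
heat outside; values above 1 mean the explanation concentrates on the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .constitutions import Constitution
from .features_deep import ResidualBackbone, masked_input
from .nn import Tensor
from .synthetic import TongueSample

__all__ = ["Heatmap", "gradcam", "localization_score"]

LOCALIZATION_CAP = 1e6


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    target_class: Constitution
    layer_name: str


def gradcam(
    model: ResidualBackbone,
    image_or_sample,
    target_class: Constitution,
    layer: str = "last_conv",
) -> Heatmap:
    """Class-evidence heatmap for ``target_class`` at the given layer.

    Only the final convolutional stage (``"last_conv"``) is exposed as a
    target layer; it is the standard choice and the only one the backbone
    retains activations for.
    """
    if layer != "last_conv":
        raise ValueError(f"unknown layer {layer!r}; available: 'last_conv'")
    if isinstance(image_or_sample, TongueSample):
        x = masked_input(image_or_sample)
    else:
        x = np.asarray(image_or_sample, dtype=np.float32)
        if x.max() > 1.5:
            x = x / 255.0
    h, w = x.shape[:2]
    xb = Tensor(x.transpose(2, 0, 1)[None], requires_grad=True)
    model.eval()
    logits = model.forward(xb, keep_conv=True)
    model.train()
    act = model.last_conv_act
    if target_class not in model.class_labels:
        raise ValueError(f"model was not trained on class {target_class}")
    k = model.class_labels.index(target_class)
    seed = np.zeros_like(logits.data)
    seed[0, k] = 1.0
    logits.backward(seed)
    grads = act.grad[0]  # (C, h', w')
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    cam = resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False)
    top = cam.max()
    if top > 0:
        cam = cam / top
    return Heatmap(values=cam.astype(np.float64), target_class=target_class, layer_name=layer)


def localization_score(heatmap: Heatmap | np.ndarray, lesion_mask: np.ndarray) -> float:
    """Mean heat inside the lesion mask over mean heat outside.

    Returns 1.0 for a flat (or all-zero) map, and caps at 1e6 when all heat
    falls inside the lesion.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    mask = np.asarray(lesion_mask).astype(bool)
    if values.shape != mask.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("empty lesion mask")
    inside = float(values[mask].mean())
    outside = float(values[~mask].mean()) if (~mask).any() else 0.0
    if outside == 0.0:
        return 1.0 if inside == 0.0 else LOCALIZATION_CAP
    return inside / outside
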