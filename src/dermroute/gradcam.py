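"""Gradient-weighted class activation mapping (Grad-CAM).

For a class score :math:`y_c` (the pre-softmax logit) and the K feature
maps :math:`A_k` of the network's last convolutional stage, the map is

    L_c = ReLU( sum_k w_k^c A_k ),   w_k^c = spatial mean of dy_c/dA_k.

The raw u x v map is kept for quantitative use; for display it is
bicubically upsampled to the input resolution, min-max scaled to [0, 1]
and blended with the image through a matplotlib colormap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image

from .nn import Conv2D, ReLU, Sequential

__all__ = ["HeatMap", "gradcam_weights", "gradcam_map", "explain", "overlay"]


@dataclass(frozen=True)
class HeatMap:
    """Non-negative class-discriminative localization map."""

    values: np.ndarray  # (u, v), >= 0
    class_label: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("heat-map values must be non-negative")


def gradcam_weights(grads: np.ndarray) -> np.ndarray:
    """Global-average-pool the gradient planes: (K, u, v) -> (K,)."""
    grads = np.asarray(grads, dtype=float)
    if grads.ndim != 3:
        raise ValueError(
            "expected gradients of shape (K, u, v); enable gradient capture "
            "on the classifier's last convolutional layer"
        )
    return grads.mean(axis=(1, 2))


def gradcam_map(maps: np.ndarray, weights: np.ndarray, class_label: str = "") -> HeatMap:
    """ReLU of the weighted sum of feature-map planes."""
    maps = np.asarray(maps, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if maps.ndim != 3 or weights.shape != (maps.shape[0],):
        raise ValueError(
            f"need K weights for K planes (K={maps.shape[0]}, got {weights.shape})"
        )
    combined = np.tensordot(weights, maps, axes=1)
    return HeatMap(np.maximum(combined, 0.0), class_label)


def last_conv_activation_index(model: Sequential) -> int:
    """Index of the activation following the last convolutional layer
    (the ReLU output if one directly follows the conv)."""
    conv_idx = [i for i, l in enumerate(model.layers) if isinstance(l, Conv2D)]
    if not conv_idx:
        raise ValueError("classifier has no convolutional layers; Grad-CAM unsupported")
    idx = conv_idx[-1]
    if idx + 1 < len(model.layers) and isinstance(model.layers[idx + 1], ReLU):
        idx += 1
    return idx


def explain(x: np.ndarray, classifier, class_label: str,
            layer_idx: Optional[int] = None) -> tuple[HeatMap, np.ndarray]:
    """Grad-CAM heat-map for ``class_label`` plus an RGB overlay.

    ``classifier`` is a trained player (a ``CNNClassifier``); the map is
    computed at its last convolutional stage, upsampled bicubically to
    the input resolution and min-max scaled for display.  The raw
    (unnormalised) map is returned untouched inside the ``HeatMap``.
    """
    model = classifier.model
    if layer_idx is None:
        layer_idx = last_conv_activation_index(model)
    classes = list(classifier.classes)
    if class_label not in classes:
        raise ValueError(f"{class_label!r} not among {classes}")
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[-1] == 3 and arr.shape[0] != 3:
        arr = arr.transpose(2, 0, 1)
    acts, grads = model.activation_and_gradient(
        arr[None], classes.index(class_label), layer_idx
    )
    w = gradcam_weights(grads[0])
    hm = gradcam_map(acts[0], w, class_label)
    return hm, overlay(hm, np.asarray(x))


def overlay(hm: HeatMap, image: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Render the heat-map over an HxWxC (or CxHxW) image; pure function."""
    import matplotlib

    img = np.asarray(image)
    if img.ndim == 3 and img.shape[0] == 3 and img.shape[-1] != 3:
        img = img.transpose(1, 2, 0)
    h, w = img.shape[:2]
    raw = np.asarray(hm.values, dtype=float)
    lo, hi = raw.min(), raw.max()
    norm = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    up = Image.fromarray((norm * 255).astype(np.uint8)).resize((w, h), Image.BICUBIC)
    up = np.asarray(up, dtype=float) / 255.0
    colors = matplotlib.colormaps[cmap](up)[..., :3]
    base = img.astype(float)
    if base.max() > 1.0:
        base = base / 255.0
    if base.ndim == 2:
        base = np.stack([base] * 3, axis=-1)
    blended = (1 - alpha) * base + alpha * colors
    return (np.clip(blended, 0, 1) * 255).astype(np.uint8)
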