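"""Grad-CAM: gradient-weighted class-activation heatmaps.

For a chosen convolutional feature layer with maps A_k, the weight of map k
is the spatial mean of the gradient of the target-class logit with respect
to A_k; the heatmap is ReLU(sum_k w_k A_k), bilinearly upsampled to the
input image shape and max-normalized to [0, 1] when its maximum is positive.
The target layer defaults to the post-activation output of the backbone's
last convolutional block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from femursplit.harness import FittedClassifier, _stack
from femursplit.images import LABELS, FemurImage


@dataclass
class Heatmap:
    values: np.ndarray            # >= 0, shape = input image shape
    target_class: str
    note: str = "max-normalized to [0, 1]"

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("heatmap values must be non-negative")

    @property
    def argmax_rc(self) -> tuple[int, int]:
        """(row, col) of the hottest pixel."""
        return tuple(np.unravel_index(int(np.argmax(self.values)), self.values.shape))


def grad_cam(classifier: FittedClassifier, image, target_class: str,
             layer_index: int | None = None) -> Heatmap:
    """Heatmap of the evidence for ``target_class`` on one femur image."""
    if target_class not in LABELS:
        raise ValueError(f"target_class: {target_class!r} is not one of {LABELS}")
    model = classifier.model
    if not hasattr(model, "activations") or not hasattr(model, "last_conv_index"):
        raise TypeError("backbone does not expose convolutional feature maps for Grad-CAM")
    layer = model.last_conv_index if layer_index is None else layer_index

    a = image.pixels if isinstance(image, FemurImage) else np.asarray(image)
    x = _stack([a], classifier.config.input_channels)   # same input convention as predict()
    outs = model.activations(x)
    feats = outs[layer]                     # (1, C, h, w)
    if feats.ndim != 4:
        raise TypeError(f"layer {layer} does not produce spatial feature maps")
    logits = outs[-1]
    # gradient of the pre-softmax class score, per the original formulation
    dlogits = np.zeros_like(logits)
    dlogits[0, LABELS.index(target_class)] = 1.0
    grad = model.backward(dlogits, to_index=layer)     # d score / d feats

    weights = grad[0].mean(axis=(1, 2))                # (C,)
    cam = np.maximum((weights[:, None, None] * feats[0]).sum(axis=0), 0.0)
    cam = _sk_resize(cam, a.shape, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return Heatmap(values=cam, target_class=target_class)


def save_overlay(heatmap: Heatmap, image, path: str, alpha: float = 0.45) -> str:
    """Render the heatmap over the grayscale input (cosmetic output)."""
    import matplotlib
    matplotlib.use("Agg")

    a = image.pixels if isinstance(image, FemurImage) else np.asarray(image, dtype=float)
    a = a / a.max() if a.max() > 0 else a
    base = np.repeat(a[:, :, None], 3, axis=2)
    color = matplotlib.colormaps["viridis"](heatmap.values)[:, :, :3]
    overlay = (1 - alpha) * base + alpha * color
    from femursplit import io as fio
    import imageio.v3 as iio
    import os
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    iio.imwrite(path, (np.clip(overlay, 0, 1) * 255).astype(np.uint8))
    return path


def point_in_box(rc: tuple[int, int], box: tuple[int, int, int, int],
                 margin: int = 0) -> bool:
    """Is (row, col) inside the half-open box, dilated by ``margin`` pixels?"""
    r, c = rc
    r0, c0, r1, c1 = box
    return (r0 - margin) <= r < (r1 + margin) and (c0 - margin) <= c < (c1 + margin)
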