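"""Crop-based augmentation and final equalize/resize.

Training images are multiplied six-fold: the original plus five crops whose
windows are 10% smaller in each linear dimension, anchored flush to the four
corners and the center, each rescaled back to the original size by bilinear
interpolation.  Crops are deterministic (fixed fields, no jitter) and are
applied to training folds only — evaluation images receive equalization and
resizing alone.  The finishing steps are global histogram equalization
(256 bins) and a resize to 500×300 (height×width), matching the ~1.7:1
aspect of a half hip film.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from skimage import exposure
from skimage.transform import resize as _sk_resize

from femursplit.images import FemurImage

#: Crop fields in a fixed order, with the short codes used in manifests.
CROP_ANCHORS = ("top_right", "bottom_right", "bottom_left", "top_left", "center")
ANCHOR_CODES = {"top_right": "tr", "bottom_right": "br", "bottom_left": "bl",
                "top_left": "tl", "center": "ctr"}

FINAL_HEIGHT = 500
FINAL_WIDTH = 300


def crop_window(anchor: str, height: int, width: int,
                fraction: float = 0.9) -> tuple[int, int, int, int]:
    """Window ``(row0, col0, window_height, window_width)`` for one crop field.

    The window is ``round(fraction * dim)`` on each axis, flush against the
    named corner, or centered (floor of the half-margin on odd remainders).
    """
    if anchor not in CROP_ANCHORS:
        raise ValueError(f"anchor: {anchor!r} is not one of {CROP_ANCHORS}")
    wh = int(round(fraction * height))
    ww = int(round(fraction * width))
    r0 = 0 if anchor.startswith("top") else (
        (height - wh) // 2 if anchor == "center" else height - wh)
    c0 = 0 if anchor.endswith("left") else (
        (width - ww) // 2 if anchor == "center" else width - ww)
    return r0, c0, wh, ww


def _resize01(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = _sk_resize(a, shape, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _scale_bbox(box, sr: float, sc: float, shape):
    if box is None:
        return None
    r0, c0, r1, c1 = box
    H, W = shape
    return (max(0, int(np.floor(r0 * sr))), max(0, int(np.floor(c0 * sc))),
            min(H, int(np.ceil(r1 * sr))), min(W, int(np.ceil(c1 * sc))))


def crop_augment(f: FemurImage, fraction: float = 0.9) -> list[FemurImage]:
    """Original plus five fixed-field crops rescaled to the original shape.

    Labels are inherited unchanged; each output's ``meta['augmentation']`` is
    ``orig`` or the crop code.  Phantom lesion boxes are remapped through the
    crop-and-rescale geometry.
    """
    H, W = f.shape
    if H < 10 or W < 10:
        raise ValueError(f"image too small to crop-augment: {f.shape}")
    out = [replace(f, meta={**f.meta, "augmentation": "orig"})]
    box = f.meta.get("lesion_bbox")
    for anchor in CROP_ANCHORS:
        r0, c0, wh, ww = crop_window(anchor, H, W, fraction)
        window = f.pixels[r0:r0 + wh, c0:c0 + ww]
        new_box = None
        if box is not None:
            br0, bc0, br1, bc1 = box
            shifted = (br0 - r0, bc0 - c0, br1 - r0, bc1 - c0)
            new_box = _scale_bbox(shifted, H / wh, W / ww, (H, W))
        out.append(replace(f, pixels=_resize01(window, (H, W)),
                           meta={**f.meta, "augmentation": ANCHOR_CODES[anchor],
                                 "lesion_bbox": new_box}))
    return out


def equalize(f: FemurImage) -> FemurImage:
    """Global histogram equalization (256 bins) balancing brightness/darkness.

    The mapping is the (monotone non-decreasing) empirical CDF, so pixel
    order is preserved and equal inputs stay equal; output is in [0, 1].
    """
    eq = exposure.equalize_hist(np.asarray(f.pixels, dtype=np.float64), nbins=256)
    return replace(f, pixels=np.clip(eq, 0.0, 1.0))


def resize_final(f: FemurImage, height: int = FINAL_HEIGHT,
                 width: int = FINAL_WIDTH) -> FemurImage:
    """Bilinear resize to the network input geometry (default 500×300)."""
    H, W = f.shape
    box = _scale_bbox(f.meta.get("lesion_bbox"), height / H, width / W, (height, width))
    return replace(f, pixels=_resize01(np.asarray(f.pixels, dtype=np.float64), (height, width)),
                   meta={**f.meta, "lesion_bbox": box})


def finish(f: FemurImage, height: int = FINAL_HEIGHT, width: int = FINAL_WIDTH) -> FemurImage:
    """Equalize then resize — the finishing steps shared by train and eval paths."""
    return resize_final(equalize(f), height, width)


def augment_training_set(femurs, height: int = FINAL_HEIGHT, width: int = FINAL_WIDTH,
                         fraction: float = 0.9) -> list[FemurImage]:
    """Six-fold crop augmentation followed by equalize+resize (training folds only)."""
    out: list[FemurImage] = []
    for f in femurs:
        out.extend(finish(c, height, width) for c in crop_augment(f, fraction))
    return out


def prepare_eval_set(femurs, height: int = FINAL_HEIGHT, width: int = FINAL_WIDTH) -> list[FemurImage]:
    """Equalize+resize only — no test-time augmentation."""
    return [finish(f, height, width) for f in femurs]
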