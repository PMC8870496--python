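"""Anatomy-aware preprocessing: one bilateral radiograph → two left-aligned femur images.

Pipeline order: min-max normalization → binarization (every non-zero pixel
becomes foreground) → morphological opening to remove artifacts such as the
"R" laterality marker → midline detection from the left/right extremes of
the remaining body area → vertical split at the midline with the right half
mirrored so every femur shares the same (left-side) orientation.

Conventions (the source data leaves them open; they are fixed here and
recorded in output metadata):

* Binarization thresholds the *raw* image at "> 0"; after min-max
  normalization the minimum pixel is exactly 0, so the rule is equivalent on
  either, but the raw image is robust to constant-exposure degenerates.
* The midline is ``floor((leftmost + rightmost) / 2)`` of the foreground
  column span, and the midline column itself belongs to the right half.
* "Left" means the image-left half kept as-is; the image-right half is
  mirrored, with ``flipped=True`` recorded so the convention is invertible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

from femursplit.images import FemurImage, Radiograph


@dataclass
class PreprocessConfig:
    kernel_size: int = 15          # square opening footprint, px at native resolution
    keep_largest_component: bool = True

    def validate(self) -> "PreprocessConfig":
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size: must be >= 1, got {self.kernel_size}")
        return self


def min_max_normalize(r: Radiograph) -> Radiograph:
    """Linearly map the image's own min→0 and max→1 (order-preserving).

    Compensates for per-image exposure/brightness differences.  A constant
    image maps to all zeros with a warning.
    """
    x = np.asarray(r.pixels, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn(f"{r.image_id}: constant image (degenerate exposure); "
                      "min-max normalization returns all zeros", stacklevel=2)
        y = np.zeros_like(x)
    else:
        y = (x - lo) / (hi - lo)
    return replace(r, pixels=y, meta={**r.meta, "normalized": True})


def binarize(r: Radiograph) -> np.ndarray:
    """Foreground mask: 1 wherever the raw pixel value is strictly positive."""
    return (np.asarray(r.pixels) > 0).astype(np.uint8)


def remove_artifacts(mask: np.ndarray, kernel_size: int = 15,
                     keep_largest_component: bool = True) -> np.ndarray:
    """Morphological opening with a square kernel, then (optionally) keep only
    the largest connected component.

    Opening erases structures thinner than the kernel (markers, letters,
    noise); the largest-component guard removes compact artifacts thicker
    than the kernel, which opening alone cannot.
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size: must be >= 1, got {kernel_size}")
    m = np.asarray(mask).astype(bool)
    if kernel_size > 1:
        m = ndimage.binary_opening(m, structure=np.ones((kernel_size, kernel_size), dtype=bool))
    if not m.any():
        raise RuntimeError("no body region detected (foreground empty after opening)")
    if keep_largest_component:
        lab, n = cc_label(m, return_num=True)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            m = lab == int(np.argmax(sizes))
    return m.astype(np.uint8)


def find_midline(mask: np.ndarray) -> int:
    """Column halfway between the leftmost and rightmost foreground columns
    (floor on ties); strictly inside the foreground span."""
    m = np.asarray(mask).astype(bool)
    occupied = np.flatnonzero(m.any(axis=0))
    if occupied.size == 0:
        raise RuntimeError("empty mask: cannot locate body midline")
    return int((occupied[0] + occupied[-1]) // 2)


def _shift_bbox_left(box, midline: int):
    return box  # left-half coordinates are unchanged


def _flip_bbox_right(box, width: int):
    r0, c0, r1, c1 = box
    # the mirrored right half indexes original column c at local j = width-1-c,
    # so [c0, c1) maps directly to local [width-c1, width-c0)
    return (r0, width - c1, r1, width - c0)


def split_and_flip(r: Radiograph, midline: int) -> tuple[FemurImage, FemurImage]:
    """Split at the midline column and mirror the right half.

    Left half = columns ``[0, midline)`` unchanged; right half = columns
    ``[midline, width)`` mirrored horizontally.  Each output inherits the
    label of its image side.  Phantom lesion boxes are mapped into each
    half's own coordinates.
    """
    width = r.shape[1]
    if not (0 < midline < width - 1):
        raise ValueError(f"midline: {midline} is at the image border (width {width})")
    px = np.asarray(r.pixels)
    boxes = r.meta.get("lesion_boxes", {})

    def _half_box(side):
        box = boxes.get(side)
        if box is None:
            return None
        if side == "left":
            return _shift_bbox_left(box, midline)
        return _flip_bbox_right(box, width)

    left = FemurImage(pixels=px[:, :midline].copy(), source_image_id=r.image_id,
                      source_side="left", label=r.left_label, flipped=False,
                      meta={"midline": midline, "lesion_bbox": _half_box("left")})
    right = FemurImage(pixels=px[:, midline:][:, ::-1].copy(), source_image_id=r.image_id,
                       source_side="right", label=r.right_label, flipped=True,
                       meta={"midline": midline, "lesion_bbox": _half_box("right")})
    return left, right


def preprocess_radiograph(r: Radiograph,
                          config: PreprocessConfig | None = None) -> tuple[FemurImage, FemurImage]:
    """Full four-stage pipeline on one radiograph."""
    cfg = (config or PreprocessConfig()).validate()
    try:
        normalized = min_max_normalize(r)
        mask = binarize(r)
        body = remove_artifacts(mask, cfg.kernel_size, cfg.keep_largest_component)
        midline = find_midline(body)
        return split_and_flip(normalized, midline)
    except (ValueError, RuntimeError) as exc:
        raise type(exc)(f"[{r.image_id}] {exc}") from exc


def preprocess_cohort(radiographs, config: PreprocessConfig | None = None,
                      out_dir=None, bit_depth: int = 16
                      ) -> tuple[list[FemurImage], pd.DataFrame]:
    """Preprocess every radiograph of a cohort; 2 femur images per input.

    Returns the femur images and a femur-level manifest (femur_id,
    source_image_id, side, flipped, label, path).  PNGs named
    ``{image_id}_{L|R}.png`` are written if ``out_dir`` is given.
    """
    if out_dir is not None:
        import os
        from femursplit import io as fio
        os.makedirs(out_dir, exist_ok=True)

    femurs: list[FemurImage] = []
    records = []
    for r in radiographs:
        for f in preprocess_radiograph(r, config):
            path = ""
            if out_dir is not None:
                import os
                from femursplit import io as fio
                path = os.path.join(str(out_dir), f"{f.femur_id}.png")
                fio.save_png(f.pixels, path, bit_depth=bit_depth)
            femurs.append(f)
            records.append({"femur_id": f.femur_id, "source_image_id": f.source_image_id,
                            "side": f.source_side, "flipped": f.flipped,
                            "label": f.label, "path": path})
    manifest = pd.DataFrame.from_records(
        records, columns=["femur_id", "source_image_id", "side", "flipped", "label", "path"])
    if out_dir is not None:
        import os
        manifest.to_csv(os.path.join(str(out_dir), "femur_manifest.csv"), index=False)
    return femurs, manifest
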