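"""Core in-memory containers for radiographs and single-femur images.

Conventions
-----------
* Images are 2-D ``numpy`` arrays indexed ``[row, column]``; row 0 is the top.
* A :class:`Radiograph` holds raw (non-negative, finite) intensities; after
  min-max normalization intensities live in ``[0, 1]``.
* ``left`` / ``right`` refer to *image* coordinates (the left half of the
  film), not the patient's anatomical side: AP films mirror the patient, and
  the ``flipped`` flag on :class:`FemurImage` keeps the convention invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The three diagnostic labels, in fixed class order (index 0, 1, 2).
LABELS: tuple[str, ...] = ("no_tumor", "benign", "malignant")

#: Severity order used when a whole radiograph must carry a single label.
SEVERITY: dict[str, int] = {"no_tumor": 0, "benign": 1, "malignant": 2}

SIDES: tuple[str, str] = ("left", "right")


def _check_label(label: str, fieldname: str) -> str:
    if label not in LABELS:
        raise ValueError(f"{fieldname}: {label!r} is not one of {LABELS}")
    return label


@dataclass
class Radiograph:
    """One bilateral AP hip radiograph with per-side ground-truth labels.

    ``meta`` carries provenance and, for phantom images, ground truth such as
    the true body-center column and per-side lesion bounding boxes
    ``(row0, col0, row1, col1)`` (half-open, full-image coordinates).
    """

    pixels: np.ndarray
    image_id: str
    left_label: str = "no_tumor"
    right_label: str = "no_tumor"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels: expected a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels: intensities must be finite")
        if np.min(self.pixels) < 0:
            raise ValueError("pixels: intensities must be >= 0")
        _check_label(self.left_label, "left_label")
        _check_label(self.right_label, "right_label")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def label_for_side(self, side: str) -> str:
        if side not in SIDES:
            raise ValueError(f"side: {side!r} is not one of {SIDES}")
        return self.left_label if side == "left" else self.right_label

    @property
    def radiograph_label(self) -> str:
        """Most severe per-side label (malignant > benign > no_tumor)."""
        return max((self.left_label, self.right_label), key=SEVERITY.__getitem__)


@dataclass
class FemurImage:
    """One single-femur half-image in the shared (left-side) orientation.

    Invariant: ``flipped`` is True iff ``source_side == "right"`` — right
    halves are mirrored so all femora present the same anatomy orientation.
    """

    pixels: np.ndarray
    source_image_id: str
    source_side: str
    label: str
    flipped: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels: expected a non-empty 2-D grid")
        if self.source_side not in SIDES:
            raise ValueError(f"source_side: {self.source_side!r} is not one of {SIDES}")
        _check_label(self.label, "label")
        if self.flipped != (self.source_side == "right"):
            raise ValueError("flipped: must be True exactly when source_side == 'right'")

    @property
    def femur_id(self) -> str:
        return f"{self.source_image_id}_{'R' if self.source_side == 'right' else 'L'}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def lesion_bbox(self) -> Optional[tuple[int, int, int, int]]:
        """Ground-truth lesion box ``(row0, col0, row1, col1)`` in this image's
        own coordinates, or None (phantom images only)."""
        return self.meta.get("lesion_bbox")
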