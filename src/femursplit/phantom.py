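"""Synthetic bilateral AP hip radiograph phantoms with ground truth.

The phantom emulates the features of clinical hip films that the pipeline
must cope with, without attempting anatomical realism:

* a bright body region (an ellipse) on an *exactly zero* background, shifted
  horizontally because patients are rarely centered on the film;
* two "femur" structures (head circle + shaft) symmetric about the body axis;
* an optional thin, bright "R"-style laterality marker in an image corner —
  it survives binarization and is only removed by morphological opening;
* per-image exposure variation (each image occupies its own intensity band);
* per-femur lesions: bright/blastic or dark/lytic elliptical perturbations
  with a configurable transition-zone softness (sharp edges read as benign,
  wide hazy edges as malignant).

Every generated image carries its ground truth (true body-center column,
per-side labels, lesion bounding boxes) so downstream stages can be verified
exactly.  Generation is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from femursplit.images import LABELS, Radiograph

LESION_KINDS = ("none", "benign", "malignant")

#: Default lesion geometry/contrast per severity.  Sizes are fractions of the
#: image width; amplitude is added to the [0, 1] tissue value (negative =
#: lytic/dark); softness is the logistic transition width relative to the
#: lesion radius (narrow zone of transition = benign-looking sharp edge).
LESION_DEFAULTS = {
    "benign": {"size_frac": 0.034, "amplitude": +0.50, "softness": 0.06},
    "malignant": {"size_frac": 0.055, "amplitude": -0.55, "softness": 0.45},
}

# Body/femur layout as fractions of (H, W); the ellipse half-width 0.24*W
# keeps the whole body inside the frame for |body_offset_fraction| < 0.25.
_BODY_HALF_HEIGHT = 0.46
_BODY_HALF_WIDTH = 0.24
_FEMUR_DXC = 0.12          # femur axis offset from body center, frac of W
_HEAD_ROW = 0.45           # femoral head center row, frac of H
_HEAD_RADIUS = 0.055       # frac of W
_SHAFT_HALF_WIDTH = 0.030  # frac of W


@dataclass
class PhantomSpec:
    """Parameters of a single synthetic radiograph."""

    image_height: int = 850
    image_width: int = 500
    body_offset_fraction: float = 0.0
    exposure_range: tuple[float, float] = (0.35, 1.0)
    marker: bool = True
    marker_corner: str = "top_left"
    lesion_left: str = "none"
    lesion_right: str = "none"
    lesion_params: Optional[dict] = None   # per-severity overrides of LESION_DEFAULTS
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.image_height <= 0:
            raise ValueError(f"image_height: must be > 0, got {self.image_height}")
        if self.image_width <= 0:
            raise ValueError(f"image_width: must be > 0, got {self.image_width}")
        lo, hi = self.exposure_range
        if not (0 <= lo < hi):
            raise ValueError(f"exposure_range: need 0 <= min < max, got {self.exposure_range}")
        if abs(self.body_offset_fraction) >= 0.25:
            raise ValueError(
                f"body_offset_fraction: |offset| must be < 0.25 so both femora stay "
                f"in frame, got {self.body_offset_fraction}"
            )
        if self.marker_corner not in ("top_left", "top_right"):
            raise ValueError(f"marker_corner: got {self.marker_corner!r}")
        for name in ("lesion_left", "lesion_right"):
            if getattr(self, name) not in LESION_KINDS:
                raise ValueError(f"{name}: {getattr(self, name)!r} is not one of {LESION_KINDS}")
        return self

    def lesion_style(self, kind: str) -> dict:
        style = dict(LESION_DEFAULTS[kind])
        if self.lesion_params and kind in self.lesion_params:
            style.update(self.lesion_params[kind])
        return style


@dataclass
class DatasetComposition:
    """Radiograph-level class counts of a synthetic cohort."""

    n_malignant_radiographs: int = 89
    n_bilateral_malignant: int = 5
    n_benign_radiographs: int = 120
    n_no_tumor_radiographs: int = 60
    seed: int = 0

    def validate(self) -> "DatasetComposition":
        for name in ("n_malignant_radiographs", "n_bilateral_malignant",
                     "n_benign_radiographs", "n_no_tumor_radiographs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.n_bilateral_malignant > self.n_malignant_radiographs:
            raise ValueError(
                "n_bilateral_malignant: cannot exceed n_malignant_radiographs "
                f"({self.n_bilateral_malignant} > {self.n_malignant_radiographs})"
            )
        return self

    @property
    def n_total(self) -> int:
        return (self.n_malignant_radiographs + self.n_benign_radiographs
                + self.n_no_tumor_radiographs)


def _soft_ellipse(rows: np.ndarray, cols: np.ndarray, center: tuple[float, float],
                  radii: tuple[float, float], softness: float) -> np.ndarray:
    """Logistic-edged ellipse weight in [0, 1]; ``softness`` is the transition
    width relative to the radius (→0 gives a hard edge)."""
    d = np.sqrt(((rows - center[0]) / radii[0]) ** 2 + ((cols - center[1]) / radii[1]) ** 2)
    s = max(softness, 1e-3)
    return 1.0 / (1.0 + np.exp((d - 1.0) / s))


def _draw_marker(img: np.ndarray, value: float, corner: str) -> None:
    """Thin 'R'-like strokes of bright pixels in an upper corner.

    Strokes are a few pixels wide so a morphological opening with a modest
    square kernel erases them while the body blob survives.
    """
    H, W = img.shape
    h = max(12, int(round(0.05 * H)))
    w = max(8, int(round(0.03 * W)))
    t = max(2, int(round(0.006 * W)))          # stroke thickness
    r0 = max(2, int(round(0.02 * H)))
    c0 = max(2, int(round(0.02 * W))) if corner == "top_left" else W - w - max(2, int(round(0.02 * W)))
    # vertical stem
    img[r0:r0 + h, c0:c0 + t] = value
    # top and middle horizontal bars
    img[r0:r0 + t, c0:c0 + w] = value
    img[r0 + h // 2:r0 + h // 2 + t, c0:c0 + w] = value
    # right stroke of the loop
    img[r0:r0 + h // 2, c0 + w - t:c0 + w] = value
    # diagonal leg
    for k in range(h // 2):
        rr = r0 + h // 2 + k
        cc = c0 + t + int(round((w - 2 * t) * k / max(1, h // 2 - 1)))
        img[rr:rr + t, cc:cc + t] = value


def _lesion_label(kind: str) -> str:
    return "no_tumor" if kind == "none" else kind


def generate_radiograph(spec: PhantomSpec) -> Radiograph:
    """Render one phantom radiograph; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    rows, cols = np.ogrid[0:H, 0:W]
    cx = W / 2.0 + spec.body_offset_fraction * W
    cy = H / 2.0

    body = (((rows - cy) / (_BODY_HALF_HEIGHT * H)) ** 2
            + ((cols - cx) / (_BODY_HALF_WIDTH * W)) ** 2) <= 1.0

    # soft-tissue base + low-frequency exposure texture
    v = np.full((H, W), 0.42)
    coarse = rng.normal(0.0, 1.0, size=(6, 4))
    texture = np.kron(coarse, np.ones((H // 6 + 1, W // 4 + 1)))[:H, :W]
    v += 0.025 * texture
    v += 0.04 * np.cos(np.pi * (np.arange(H)[:, None] - cy) / H)

    lesion_boxes: dict[str, Optional[tuple[int, int, int, int]]] = {"left": None, "right": None}
    for side, sign in (("left", -1.0), ("right", +1.0)):
        ccol = cx + sign * _FEMUR_DXC * W
        crow = _HEAD_ROW * H
        # femoral head
        v += 0.22 * _soft_ellipse(rows, cols, (crow, ccol),
                                  (_HEAD_RADIUS * W, _HEAD_RADIUS * W), 0.05)
        # shaft below the head
        shaft_top = crow
        shaft = ((cols - ccol) / (_SHAFT_HALF_WIDTH * W)) ** 2 <= 1.0
        shaft = shaft & (rows >= shaft_top) & (rows <= 0.92 * H)
        v += 0.16 * shaft

        kind = spec.lesion_left if side == "left" else spec.lesion_right
        if kind != "none":
            style = spec.lesion_style(kind)
            ar = style["size_frac"] * W * 1.25
            ac = style["size_frac"] * W
            # anywhere in the head/neck/trochanter-to-proximal-shaft band
            lr = crow + rng.uniform(-0.03, 0.25) * H
            lc = ccol + rng.uniform(-0.02, 0.02) * W
            core = _soft_ellipse(rows, cols, (lr, lc), (ar, ac), style["softness"])
            v += style["amplitude"] * core * body
            if style["amplitude"] < 0:
                # lytic lesions carry a faint sclerotic margin at the zone of
                # transition, as destroyed bone abuts reactive bone
                rim = _soft_ellipse(rows, cols, (lr, lc), (ar * 1.3, ac * 1.3),
                                    style["softness"]) - core
                v += 0.35 * abs(style["amplitude"]) * np.maximum(rim, 0.0) * body
            rf = 1.3 if style["amplitude"] < 0 else 1.0   # rim is part of a lytic lesion
            lesion_boxes[side] = (int(np.floor(lr - rf * ar)), int(np.floor(lc - rf * ac)),
                                  int(np.ceil(lr + rf * ar)) + 1, int(np.ceil(lc + rf * ac)) + 1)

    emin, emax = spec.exposure_range
    img = np.zeros((H, W))
    vb = np.clip(v, 0.02, 1.0)
    # body pixels must stay strictly positive even at emin == 0 and after
    # 16-bit quantization, so background-0 remains an exact foreground test
    img[body] = np.maximum(emin + (emax - emin) * vb[body], 1.5 / 65535.0)
    if spec.marker:
        _draw_marker(img, emax, spec.marker_corner)

    meta = {
        "body_center_col": cx,
        "body_mask": body,
        "lesion_boxes": lesion_boxes,
        "marker": spec.marker,
        "exposure_range": (emin, emax),
        "seed": spec.seed,
    }
    return Radiograph(pixels=img, image_id=f"phantom_{spec.seed}",
                      left_label=_lesion_label(spec.lesion_left),
                      right_label=_lesion_label(spec.lesion_right),
                      meta=meta)


def generate_cohort(comp: DatasetComposition,
                    spec_template: Optional[PhantomSpec] = None,
                    out_dir=None,
                    offset_range: tuple[float, float] = (-0.12, 0.12),
                    bit_depth: int = 16) -> tuple[list[Radiograph], pd.DataFrame]:
    """Generate a full cohort matching a radiograph-level composition.

    All bilateral-tumor radiographs are malignant on both sides (the class
    counts only balance under that assignment); every other tumor radiograph
    carries its lesion on a uniformly random single side.  Returns the images
    and the manifest; if ``out_dir`` is given, PNGs and ``manifest.csv`` are
    written there.
    """
    comp.validate()
    template = (spec_template or PhantomSpec()).validate()
    rng = np.random.default_rng(comp.seed)

    plans: list[tuple[str, str]] = []      # (lesion_left, lesion_right)
    for i in range(comp.n_malignant_radiographs):
        if i < comp.n_bilateral_malignant:
            plans.append(("malignant", "malignant"))
        else:
            side = rng.choice(["left", "right"])
            plans.append(("malignant", "none") if side == "left" else ("none", "malignant"))
    for _ in range(comp.n_benign_radiographs):
        side = rng.choice(["left", "right"])
        plans.append(("benign", "none") if side == "left" else ("none", "benign"))
    plans.extend(("none", "none") for _ in range(comp.n_no_tumor_radiographs))

    if out_dir is not None:
        from femursplit import io as fio
        import os
        os.makedirs(out_dir, exist_ok=True)

    radiographs: list[Radiograph] = []
    records = []
    width = len(str(max(comp.n_total, 1)))
    for i, (ll, lr) in enumerate(plans):
        spec = dataclasses.replace(
            template,
            lesion_left=ll,
            lesion_right=lr,
            body_offset_fraction=float(rng.uniform(*offset_range)),
            exposure_range=(float(rng.uniform(0.25, 0.45)), float(rng.uniform(0.85, 1.0))),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        r = generate_radiograph(spec)
        r.image_id = f"r{i:0{width}d}"
        path = ""
        if out_dir is not None:
            import os
            path = os.path.join(str(out_dir), f"{r.image_id}.png")
            fio.save_png(r.pixels, path, bit_depth=bit_depth)
        radiographs.append(r)
        records.append({
            "image_id": r.image_id,
            "path": path,
            "left_label": r.left_label,
            "right_label": r.right_label,
            "bilateral_flag": (r.left_label != "no_tumor" and r.right_label != "no_tumor"),
        })
    manifest = pd.DataFrame.from_records(
        records, columns=["image_id", "path", "left_label", "right_label", "bilateral_flag"])
    if out_dir is not None:
        import os
        manifest.to_csv(os.path.join(str(out_dir), "manifest.csv"), index=False)
    return radiographs, manifest


def femur_label_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """Per-femur ground-truth label totals from a cohort manifest."""
    counts = {lab: 0 for lab in LABELS}
    for _, row in manifest.iterrows():
        counts[row["left_label"]] += 1
        counts[row["right_label"]] += 1
    return counts
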