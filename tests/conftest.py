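"""Shared fixtures: small phantoms, preprocessed femur banks, trained models.

Phantoms are generated at 170×100 (same 1.7:1 aspect as the native 850×500
default) with a 5-px opening kernel so the whole suite runs quickly on one
CPU.  "Strong" lesions (larger, higher contrast than the generator defaults)
are the separable condition used by the learning-sanity and Grad-CAM checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import femursplit as fs
from femursplit.augment import crop_augment, finish
from femursplit.harness import TrainConfig, train_fold

PH, PW = 170, 100          # small-phantom geometry (1.7:1)
KERNEL = 5                 # opening kernel matched to the small marker strokes
NET_H, NET_W = 50, 30      # classifier input at this scale

#: high-contrast lesion condition for the separability/localization checks
STRONG_LESIONS = {
    "benign": {"size_frac": 0.09, "amplitude": 0.55, "softness": 0.05},
    "malignant": {"size_frac": 0.13, "amplitude": -0.6, "softness": 0.4},
}

#: desk-scale training settings for the tiny numpy backbone
CAM_TRAIN = dict(epochs=12, initial_lr=0.01, momentum=0.9, weight_decay=1e-3,
                 backbone_kwargs={"widths": (4, 8)})


def small_spec(**kw) -> fs.PhantomSpec:
    base = dict(image_height=PH, image_width=PW)
    base.update(kw)
    return fs.PhantomSpec(**base)


@pytest.fixture(scope="session")
def femur_bank():
    """150 preprocessed single-femur images with strong right-side lesions
    (balanced no_tumor/benign/malignant), split 120 train / 30 eval."""
    femurs = []
    for i in range(150):
        kind = ["none", "benign", "malignant"][i % 3]
        spec = small_spec(seed=100 + i, lesion_left="none", lesion_right=kind,
                          lesion_params=STRONG_LESIONS)
        r = fs.generate_radiograph(spec)
        _, right = fs.preprocess_radiograph(r, fs.PreprocessConfig(kernel_size=KERNEL))
        femurs.append(right)
    return femurs[:120], femurs[120:]


@pytest.fixture(scope="session")
def cam_classifier(femur_bank):
    """Tiny CNN trained on the crop-augmented strong-lesion bank (seed 0)."""
    train, _ = femur_bank
    imgs, labels = [], []
    for f in train:
        for c in crop_augment(f):
            imgs.append(finish(c, NET_H, NET_W))
            labels.append(c.label)
    return train_fold(imgs, labels, TrainConfig(seed=0, **CAM_TRAIN))


@pytest.fixture(scope="session")
def eval_images(femur_bank):
    _, test = femur_bank
    return [finish(f, NET_H, NET_W) for f in test]


@pytest.fixture(scope="session")
def small_cohort():
    """A 36-radiograph cohort (12 malignant / 1 bilateral / 12 benign / 12
    normal) with strong lesions, plus its manifest."""
    comp = fs.DatasetComposition(12, 1, 12, 12, seed=5)
    radiographs, manifest = fs.generate_cohort(
        comp, small_spec(lesion_params=STRONG_LESIONS))
    return radiographs, manifest
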