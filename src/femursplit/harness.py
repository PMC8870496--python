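"""Training and prediction harness for the three-label femur classifier.

The training protocol is fixed: stochastic gradient descent on cross-entropy,
50 epochs, batch size 8, learning rate starting at 0.1 and divided by 10
every 10 epochs.  The backbone is pluggable through a registry: ``tiny`` is
the in-package numpy CNN used throughout the test suite; the full-scale
names (ResNet50, Inception v3, EfficientNet-b1/2/3) are registered so a
torch-equipped deployment can slot them in, and raise a clear error here.
Backbones that require three input channels receive the grayscale plane
duplicated thrice; single-channel backbones take it as-is.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from femursplit.images import LABELS, FemurImage
from femursplit.nn import TinyCNN, cross_entropy, softmax


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    initial_lr: float = 0.1
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 10
    momentum: float = 0.0         # plain SGD by default
    weight_decay: float = 0.0
    input_channels: int = 1
    backbone: str = "tiny"
    backbone_kwargs: dict = field(default_factory=dict)
    pretrained: bool = False      # ImageNet-style initialization where the backbone supports it
    seed: int = 0

    def validate(self) -> "TrainConfig":
        for name in ("epochs",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        for name in ("batch_size", "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        if self.initial_lr <= 0 or self.lr_decay_factor <= 0:
            raise ValueError("initial_lr/lr_decay_factor: must be > 0")
        if self.input_channels not in (1, 3):
            raise ValueError(f"input_channels: must be 1 or 3, got {self.input_channels}")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone: {self.backbone!r} not in registry {sorted(BACKBONES)}")
        return self


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: initial_lr / factor**floor(epoch / decay_every)."""
    return config.initial_lr / config.lr_decay_factor ** (epoch // config.lr_decay_every)


def adapt_channels(image, n_channels: int) -> np.ndarray:
    """Stack a 2-D grayscale plane into the channel layout a backbone needs:
    1 → the plane itself, 3 → the plane duplicated thrice."""
    a = image.pixels if isinstance(image, FemurImage) else np.asarray(image)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    if n_channels == 1:
        return a[None, :, :]
    if n_channels == 3:
        return np.repeat(a[None, :, :], 3, axis=0)
    raise ValueError(f"n_channels: must be 1 or 3, got {n_channels}")


def _tiny_factory(config: TrainConfig, input_hw: tuple[int, int]):
    return TinyCNN(in_channels=config.input_channels, n_classes=len(LABELS),
                   input_hw=input_hw, seed=config.seed, **config.backbone_kwargs)


def _torch_factory(name: str) -> Callable:
    def build(config: TrainConfig, input_hw: tuple[int, int]):
        raise ImportError(
            f"backbone {name!r} requires torch/torchvision, which this installation "
            "does not provide; use backbone='tiny' or install the GPU extras")
    return build


BACKBONES: dict[str, Callable] = {
    "tiny": _tiny_factory,
    "resnet50": _torch_factory("resnet50"),
    "inception_v3": _torch_factory("inception_v3"),
    "efficientnet_b1": _torch_factory("efficientnet_b1"),
    "efficientnet_b2": _torch_factory("efficientnet_b2"),
    "efficientnet_b3": _torch_factory("efficientnet_b3"),
}


@dataclass
class PredictionRecord:
    """Per-femur classifier output consumed by the evaluation module."""

    femur_id: str
    true_label: Optional[str]
    predicted_label: str
    class_scores: tuple[float, float, float]   # (no_tumor, benign, malignant), sums to 1
    fold_index: int = 0
    inference_seconds: float = 0.0

    def __post_init__(self) -> None:
        s = float(np.sum(self.class_scores))
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"class_scores: must sum to 1 (got {s})")
        if self.predicted_label != LABELS[int(np.argmax(self.class_scores))]:
            raise ValueError("predicted_label: must be the argmax of class_scores")


@dataclass
class FittedClassifier:
    """Handle around a trained backbone: the model, its config, and the
    per-epoch (lr, loss) training log."""

    model: TinyCNN
    config: TrainConfig
    history: pd.DataFrame


def standardize(x: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance scaling — the numpy backbone's input
    convention (the analogue of a torch model's mean/std normalization)."""
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    sd = x.std(axis=(1, 2, 3), keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-6)


def _stack(images: Sequence, n_channels: int) -> np.ndarray:
    return standardize(np.stack([adapt_channels(im, n_channels) for im in images]))


def _labels_to_int(labels: Sequence[str]) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(LABELS)}
    return np.array([idx[lab] for lab in labels], dtype=np.int64)


def train_fold(images: Sequence, labels: Sequence[str],
               config: TrainConfig | None = None) -> FittedClassifier:
    """Train one backbone on one training fold under the fixed SGD schedule.

    ``images`` are FemurImages or 2-D arrays (all the same shape); ``labels``
    are the string class labels.  Deterministic given ``config.seed``.
    """
    cfg = (config or TrainConfig()).validate()
    if len(images) == 0:
        raise ValueError("training set is empty")
    y = _labels_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set covers a single class; need >= 2")
    x = _stack(images, cfg.input_channels)

    model = BACKBONES[cfg.backbone](cfg, x.shape[2:4])
    rng = np.random.default_rng(cfg.seed)
    velocity = [np.zeros_like(w) for w, _ in model.parameters()]
    log = []
    n = len(y)
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x[sel])
            loss, dlogits = cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits, to_index=-1)
            for (w, g), v in zip(model.parameters(), velocity):
                if cfg.weight_decay:
                    g += cfg.weight_decay * w
                if cfg.momentum:
                    v *= cfg.momentum
                    v += g
                    w -= lr * v
                else:
                    w -= lr * g
            epoch_loss += loss * len(sel)
        log.append({"epoch": epoch, "lr": lr, "loss": epoch_loss / n})
    history = pd.DataFrame(log, columns=["epoch", "lr", "loss"])
    return FittedClassifier(model=model, config=cfg, history=history)


def predict(classifier: FittedClassifier, images: Sequence,
            femur_ids: Sequence[str] | None = None,
            true_labels: Sequence[str] | None = None,
            fold_index: int = 0) -> list[PredictionRecord]:
    """One PredictionRecord per image, with per-image wall-clock inference time."""
    cfg = classifier.config
    records = []
    for i, im in enumerate(images):
        t0 = time.perf_counter()
        scores = softmax(classifier.model.forward(_stack([im], cfg.input_channels)))[0]
        dt = time.perf_counter() - t0
        fid = (femur_ids[i] if femur_ids is not None
               else im.femur_id if isinstance(im, FemurImage) else f"img{i:05d}")
        truth = (true_labels[i] if true_labels is not None
                 else im.label if isinstance(im, FemurImage) else None)
        records.append(PredictionRecord(
            femur_id=fid, true_label=truth,
            predicted_label=LABELS[int(np.argmax(scores))],
            class_scores=tuple(float(s) for s in scores),
            fold_index=fold_index, inference_seconds=dt))
    return records


def records_to_dataframe(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Flatten records into the predictions.csv schema."""
    return pd.DataFrame.from_records([{
        "femur_id": r.femur_id, "fold": r.fold_index,
        "true": r.true_label, "pred": r.predicted_label,
        "p_no_tumor": r.class_scores[0], "p_benign": r.class_scores[1],
        "p_malignant": r.class_scores[2], "seconds": r.inference_seconds,
    } for r in records])


def dataframe_to_records(df: pd.DataFrame) -> list[PredictionRecord]:
    records = []
    for _, row in df.iterrows():
        scores = np.array([row["p_no_tumor"], row["p_benign"], row["p_malignant"]], dtype=float)
        scores = scores / scores.sum()
        records.append(PredictionRecord(
            femur_id=str(row["femur_id"]), true_label=row.get("true"),
            predicted_label=LABELS[int(np.argmax(scores))],
            class_scores=tuple(float(s) for s in scores),
            fold_index=int(row.get("fold", 0)),
            inference_seconds=float(row.get("seconds", 0.0))))
    return records
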