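"""End-to-end orchestration: phantom cohort → preprocessing → augmentation →
cross-validated training → evaluation report.

Two schemes are supported:

* ``proposed`` — the full anatomy-aware pipeline: each radiograph is split at
  the detected body midline into two left-aligned femur images (geometry
  500×300), classified per femur.
* ``basic`` — the ablation baseline: the whole radiograph (geometry 500×500,
  no split/flip stages) is classified directly; its single label is the most
  severe per-side label (malignant > benign > no_tumor).

Cross-validation folds are stratified by label and grouped by source
radiograph, so neither an augmented copy of an image nor the contralateral
femur from the same film can leak between a fold's train and eval sets.
Desk-scale classifier inputs are downscaled copies of the scheme geometry
(default 50×30 / 50×50); the geometry contract of the saved images is
unchanged.  One seed governs every stochastic step.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedGroupKFold

from femursplit import augment as aug
from femursplit import harness, metrics
from femursplit.images import FemurImage, Radiograph
from femursplit.phantom import DatasetComposition, PhantomSpec, generate_cohort
from femursplit.preprocess import PreprocessConfig, min_max_normalize, preprocess_cohort

log = logging.getLogger("femursplit")

SCHEMES = ("proposed", "basic")
#: network input geometry (height, width) per scheme
SCHEME_GEOMETRY = {"proposed": (500, 300), "basic": (500, 500)}


@dataclass
class PipelineConfig:
    out_dir: str = "femursplit_run"
    composition: DatasetComposition = field(default_factory=DatasetComposition)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: harness.TrainConfig = field(default_factory=harness.TrainConfig)
    scheme: str = "proposed"
    augment: bool = True
    folds: int = 5
    classifier_size: Optional[tuple[int, int]] = None   # None → geometry / 10
    auc_bootstrap: int = 2000
    save_images: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme: {self.scheme!r} is not one of {SCHEMES}")
        if self.folds < 2:
            raise ValueError(f"folds: must be >= 2, got {self.folds}")
        self.composition.validate()
        self.phantom.validate()
        self.preprocess.validate()
        self.train.validate()
        return self

    def resolved_classifier_size(self) -> tuple[int, int]:
        if self.classifier_size is not None:
            return self.classifier_size
        h, w = SCHEME_GEOMETRY[self.scheme]
        return (h // 10, w // 10)

    def to_yaml(self, path: str) -> str:
        d = dataclasses.asdict(self)
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["composition"] = DatasetComposition(**d.get("composition", {}))
        d["phantom"] = PhantomSpec(**{k: _tup(v) for k, v in d.get("phantom", {}).items()})
        d["preprocess"] = PreprocessConfig(**d.get("preprocess", {}))
        d["train"] = harness.TrainConfig(**d.get("train", {}))
        if d.get("classifier_size") is not None:
            d["classifier_size"] = tuple(d["classifier_size"])
        return cls(**d)


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class _Unit:
    """One classification unit: a femur image (proposed) or a whole
    radiograph (basic), with its grouping key for fold assignment."""
    unit_id: str
    group: str
    label: str
    image: FemurImage


def _femur_units(radiographs, cfg: PipelineConfig) -> list[_Unit]:
    femurs, _ = preprocess_cohort(radiographs, cfg.preprocess)
    return [_Unit(f.femur_id, f.source_image_id, f.label, f) for f in femurs]


def _radiograph_units(radiographs) -> list[_Unit]:
    units = []
    for r in radiographs:
        n = min_max_normalize(r)
        f = FemurImage(pixels=n.pixels, source_image_id=r.image_id, source_side="left",
                       label=r.radiograph_label, flipped=False,
                       meta={"whole_radiograph": True})
        units.append(_Unit(r.image_id, r.image_id, f.label, f))
    return units


def assign_folds(units: list[_Unit], n_folds: int, seed: int) -> dict[str, int]:
    """Stratified, radiograph-grouped fold assignment: ``unit_id → fold``
    (folds numbered 1..n)."""
    y = [u.label for u in units]
    groups = [u.group for u in units]
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    mapping: dict[str, int] = {}
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros(len(units)), y, groups), start=1):
        for i in test_idx:
            mapping[units[i].unit_id] = k
    return mapping


def run_pipeline(config: PipelineConfig,
                 radiographs: Optional[list[Radiograph]] = None) -> metrics.EvalReport:
    """Run the full pipeline; returns the cross-validated evaluation report.

    Writes to ``config.out_dir``: config.yaml, manifest.csv, folds.csv,
    predictions.csv, report.csv and (pooled) roc.csv.
    """
    cfg = config.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "config.yaml"))

    if radiographs is None:
        comp = dataclasses.replace(cfg.composition, seed=cfg.seed)
        radiographs, manifest = generate_cohort(comp, cfg.phantom)
        manifest.to_csv(os.path.join(cfg.out_dir, "manifest.csv"), index=False)
        log.info("phantom: generated %d radiographs", len(radiographs))

    units = (_femur_units(radiographs, cfg) if cfg.scheme == "proposed"
             else _radiograph_units(radiographs))
    log.info("%s scheme: %d radiographs in, %d evaluation units out",
             cfg.scheme, len(radiographs), len(units))

    fold_of = assign_folds(units, cfg.folds, cfg.seed)
    pd.DataFrame([{"unit_id": u.unit_id, "group": u.group, "label": u.label,
                   "fold": fold_of[u.unit_id]} for u in units]
                 ).to_csv(os.path.join(cfg.out_dir, "folds.csv"), index=False)

    ch, cw = cfg.resolved_classifier_size()
    gh, gw = SCHEME_GEOMETRY[cfg.scheme]
    if cfg.save_images:
        img_dir = os.path.join(cfg.out_dir, "images")
        from femursplit import io as fio
        for u in units:
            fio.save_png(aug.finish(u.image, gh, gw).pixels,
                         os.path.join(img_dir, f"{u.unit_id}.png"))

    records: list[harness.PredictionRecord] = []
    for k in range(1, cfg.folds + 1):
        train_units = [u for u in units if fold_of[u.unit_id] != k]
        eval_units = [u for u in units if fold_of[u.unit_id] == k]
        if cfg.augment:
            train_imgs = []
            for u in train_units:
                train_imgs.extend(aug.finish(c, ch, cw) for c in aug.crop_augment(u.image))
        else:
            train_imgs = [aug.finish(u.image, ch, cw) for u in train_units]
        log.info("fold %d: %d train images (%d units), %d eval units",
                 k, len(train_imgs), len(train_units), len(eval_units))
        tcfg = dataclasses.replace(cfg.train, seed=(cfg.seed + 1000 * k) % 2**31)
        clf = harness.train_fold(train_imgs, [f.label for f in train_imgs], tcfg)
        eval_imgs = [aug.finish(u.image, ch, cw) for u in eval_units]
        records.extend(harness.predict(
            clf, eval_imgs, femur_ids=[u.unit_id for u in eval_units],
            true_labels=[u.label for u in eval_units], fold_index=k))

    harness.records_to_dataframe(records).to_csv(
        os.path.join(cfg.out_dir, "predictions.csv"), index=False)
    report = metrics.crossval_report(records, folds=cfg.folds,
                                     auc_bootstrap=cfg.auc_bootstrap, seed=cfg.seed)
    report.to_csv(os.path.join(cfg.out_dir, "report.csv"))
    metrics.micro_roc_curve(records).to_csv(os.path.join(cfg.out_dir, "roc.csv"), index=False)
    report.summary().to_csv(os.path.join(cfg.out_dir, "summary.csv"), index=False)
    log.info("report: %s", report.summary().to_dict(orient="records")[0])
    return report
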