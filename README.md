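# femursplit

Screening for bone tumors of the proximal femur on plain anteroposterior (AP)
hip radiographs is a natural target for automated reading: the film shows both
proximal femora almost symmetrically about the body midline, and the lesions of
interest (osteolytic = dark, osteoblastic = bright) sit in a predictable
anatomical region. `femursplit` implements a complete, testable pipeline for
this task:

1. **Anatomy-aware preprocessing** — each bilateral radiograph is min-max
   normalized, binarized (every non-zero pixel is foreground), cleaned by
   morphological opening (removing thin artifacts such as the radiopaque "R"
   laterality marker), split at the body midline detected from the foreground
   column span, and the right half mirrored so every femur shares the same
   (left-side) orientation. One radiograph becomes two single-femur images.
2. **Crop augmentation** — training images are multiplied six-fold: the
   original plus five crops 10% smaller in each dimension anchored at the four
   corners and the center, rescaled back to the original size; finished by
   global histogram equalization and a resize to 500×300 (height×width).
3. **Three-label classification** — no tumor / benign / malignant per femur,
   trained with SGD on cross-entropy under a step learning-rate schedule
   (0.1 divided by 10 every 10 epochs, batch size 8 by default). The backbone
   is pluggable; a small numpy CNN (`tiny`) ships with the package and powers
   the test suite. Grayscale planes are duplicated to three channels for
   backbones that require RGB input.
4. **Evaluation** — one-vs-rest multi-class metrics under fivefold,
   radiograph-grouped cross-validation, reported as mean ± SD:
   accuracy = Σᵢ Tᵢ / D_test, precision = ⅓ Σᵢ TPᵢ/(TPᵢ+FPᵢ),
   sensitivity = ⅓ Σᵢ TPᵢ/(TPᵢ+FNᵢ), specificity = ⅓ Σᵢ TNᵢ/(TNᵢ+FPᵢ),
   F1 = ⅓ Σᵢ 2·Pᵢ·Sᵢ/(Pᵢ+Sᵢ); micro-average ROC-AUC with a bootstrap 95% CI;
   and a Pearson chi-squared test (1 df, no continuity correction) for
   comparing the diagnostic accuracy of two raters.
5. **Grad-CAM** — gradient-weighted class-activation heatmaps localizing the
   image evidence behind a predicted class.
6. **Synthetic phantoms** — a generator of ground-truthed bilateral "hip
   radiographs" (offset body on a zero background, corner marker, per-image
   exposure band, per-femur lesions with configurable polarity, size and
   zone-of-transition softness), so every stage is testable without clinical
   data. Cohorts follow a configurable radiograph-level composition; the
   default reproduces 89 malignant (5 bilateral) + 120 benign + 60 tumor-free
   = 269 radiographs → 538 femur images with label counts 94/120/324.

An ablation harness compares this *proposed* scheme against a *basic* scheme
that classifies whole radiographs resized to 500×500 without the
split-and-flip stages.

## Worked example

```python
import femursplit as fs
from femursplit.pipeline import PipelineConfig, run_pipeline
from femursplit.harness import TrainConfig

cfg = PipelineConfig(
    out_dir="demo_run",
    composition=fs.DatasetComposition(12, 1, 12, 12),
    phantom=fs.PhantomSpec(image_height=170, image_width=100,
                           lesion_params={
                               "benign": {"size_frac": 0.09, "amplitude": 0.55, "softness": 0.05},
                               "malignant": {"size_frac": 0.13, "amplitude": -0.6, "softness": 0.4}}),
    preprocess=fs.PreprocessConfig(kernel_size=5),
    train=TrainConfig(epochs=4, initial_lr=0.01, momentum=0.9,
                      weight_decay=1e-3, backbone_kwargs={"widths": (4, 8)}),
    folds=3, seed=7)
report = run_pipeline(cfg)
print(report.summary().to_string(index=False))
```

prints (36 phantom radiographs → 72 femur images, 3-fold CV on one CPU):

```
     Accuracy   Sensitivity   Specificity     Precision      F1-Score                 AUC (micro)
0.806 ± 0.087 0.700 ± 0.044 0.868 ± 0.009 0.859 ± 0.099 0.709 ± 0.060 0.935 (95% CI, 0.886–0.977)
```

i.e. on strongly separable phantoms the cross-validated femur-level accuracy
is ~0.81 and the pooled micro-average ROC-AUC ~0.94; re-running with
`scheme="basic"` (whole radiographs, no split/flip) drops accuracy to ~0.56,
illustrating what the anatomy-aware preprocessing buys. The same objects are
available from the shell: `femursplit run-all --seed 7 --out demo_run`, plus
`phantom`, `preprocess`, `augment`, `evaluate` and `gradcam` subcommands
(`femursplit --help`).

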