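"""Three-label diagnostic metrics, fivefold aggregation, ROC-AUC, and the
accuracy chi-squared comparison.

All multi-class metrics are one-vs-rest: each class i in turn is treated as
positive and the other two as negative, giving per-class TP/FP/FN/TN, and the
reported value is the unweighted (macro) mean over the three classes:

* accuracy        = sum_i T_i / D_test          (T_i = diagonal counts)
* precision       = mean_i TP_i / (TP_i + FP_i)
* sensitivity     = mean_i TP_i / (TP_i + FN_i)
* specificity     = mean_i TN_i / (TN_i + FP_i)
* F1              = mean_i 2·P_i·S_i / (P_i + S_i)

AUC is reported on the micro-average scale (all one-vs-rest score/indicator
pairs pooled into a single ROC) with a macro mean of per-class AUCs alongside,
and a seeded bootstrap-over-samples 95% CI.  Accuracies of two raters are
compared with a Pearson chi-squared test on the 2×2 correct/incorrect table
(1 df, no continuity correction).

Degenerate one-vs-rest ratios (zero denominator) contribute 0 with a warning;
a class entirely absent from both truth and prediction is skipped and the
macro mean runs over the remaining classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import label_binarize

from femursplit.images import LABELS


@dataclass
class ConfusionMatrix3:
    """3×3 counts: ``counts[i, j]`` = samples with true class i predicted j,
    classes ordered (no_tumor, benign, malignant)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError(f"counts: expected shape (3, 3), got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise ValueError("counts: must be non-negative numbers")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_labels(cls, true_labels: Sequence[str], pred_labels: Sequence[str]) -> "ConfusionMatrix3":
        idx = {lab: i for i, lab in enumerate(LABELS)}
        c = np.zeros((3, 3), dtype=np.int64)
        for t, p in zip(true_labels, pred_labels, strict=True):
            c[idx[t], idx[p]] += 1
        return cls(c)

    @property
    def d_test(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) with class ``i`` as positive."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.d_test - tp - fp - fn
        return tp, fp, fn, tn

    def class_is_vacuous(self, i: int) -> bool:
        """True when class i never occurs in truth nor in prediction."""
        return self.counts[i, :].sum() == 0 and self.counts[:, i].sum() == 0


def accuracy(cm: ConfusionMatrix3) -> float:
    if cm.d_test == 0:
        raise ValueError("empty confusion matrix (D_test = 0)")
    return float(np.trace(cm.counts)) / cm.d_test


def _macro(cm: ConfusionMatrix3, per_class) -> float:
    if cm.d_test == 0:
        raise ValueError("empty confusion matrix (D_test = 0)")
    values = []
    for i in range(3):
        if cm.class_is_vacuous(i):
            continue
        values.append(per_class(i))
    return float(np.mean(values))


def _ratio(num: int, den: int, what: str, cls: int) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {LABELS[cls]!r} "
                      "(zero denominator); contributing 0", stacklevel=3)
        return 0.0
    return num / den


def macro_precision(cm: ConfusionMatrix3) -> float:
    def f(i):
        tp, fp, _, _ = cm.one_vs_rest(i)
        return _ratio(tp, tp + fp, "precision", i)
    return _macro(cm, f)


def macro_sensitivity(cm: ConfusionMatrix3) -> float:
    def f(i):
        tp, _, fn, _ = cm.one_vs_rest(i)
        return _ratio(tp, tp + fn, "sensitivity", i)
    return _macro(cm, f)


def macro_specificity(cm: ConfusionMatrix3) -> float:
    def f(i):
        _, fp, _, tn = cm.one_vs_rest(i)
        return _ratio(tn, tn + fp, "specificity", i)
    return _macro(cm, f)


def macro_f1(cm: ConfusionMatrix3) -> float:
    def f(i):
        tp, fp, fn, _ = cm.one_vs_rest(i)
        p = _ratio(tp, tp + fp, "precision", i)
        s = _ratio(tp, tp + fn, "sensitivity", i)
        return 0.0 if p + s == 0 else 2 * p * s / (p + s)
    return _macro(cm, f)


@dataclass
class AucResult:
    micro: float                       # headline value
    macro: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


def _truth_scores(records) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([r.true_label for r in records])
    s = np.array([r.class_scores for r in records], dtype=float)
    return y, s


def micro_roc_auc(records, n_bootstrap: int = 2000, seed: int = 0) -> AucResult:
    """Micro- and macro-average one-vs-rest ROC-AUC with a bootstrap 95% CI.

    Micro pools every (one-vs-rest indicator, score) pair into a single ROC;
    macro averages the per-class AUCs over classes present in the truth.  The
    CI is a percentile bootstrap over samples on the micro AUC.
    """
    y, s = _truth_scores(records)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 distinct true labels to compute ROC-AUC")
    micro = _micro_auc(y, s)
    macro = _macro_auc(y, s)
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = []
    for _ in range(n_bootstrap):
        sel = rng.integers(0, n, size=n)
        if len(np.unique(y[sel])) < 2:
            continue
        boots.append(_micro_auc(y[sel], s[sel]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return AucResult(micro=micro, macro=macro, ci_low=float(lo), ci_high=float(hi),
                     n_bootstrap=len(boots))


def _binarized(y: np.ndarray) -> np.ndarray:
    return label_binarize(y, classes=list(LABELS))


def _micro_auc(y: np.ndarray, s: np.ndarray) -> float:
    return float(roc_auc_score(_binarized(y).ravel(), s.ravel()))


def _macro_auc(y: np.ndarray, s: np.ndarray) -> float:
    onehot = _binarized(y)
    aucs = [roc_auc_score(onehot[:, i], s[:, i])
            for i in range(3) if len(np.unique(onehot[:, i])) == 2]
    return float(np.mean(aucs))


def micro_roc_curve(records) -> pd.DataFrame:
    """Pooled one-vs-rest ROC curve coordinates (fpr, tpr, threshold)."""
    y, s = _truth_scores(records)
    fpr, tpr, thr = roc_curve(_binarized(y).ravel(), s.ravel())
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def chi2_accuracy_compare(correct_a: int, n_a: int,
                          correct_b: int, n_b: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) comparing the
    correct/incorrect proportions of two raters.

    Closed form on the 2×2 table [[a, b], [c, d]] with rows = raters and
    columns = correct/incorrect: chi2 = n (ad − bc)² / ((a+b)(c+d)(a+c)(b+d)).
    """
    for name, val in (("n_a", n_a), ("n_b", n_b)):
        if val <= 0:
            raise ValueError(f"{name}: must be > 0")
    if not (0 <= correct_a <= n_a) or not (0 <= correct_b <= n_b):
        raise ValueError("correct counts must lie in [0, n]")
    a, b = correct_a, n_a - correct_a
    c, d = correct_b, n_b - correct_b
    n = n_a + n_b
    expected = np.outer([n_a, n_b], [(a + c) / n, (b + d) / n])
    if (expected < 1).any():
        warnings.warn("chi-squared: an expected cell count is below 1; "
                      "the asymptotic p-value is unreliable", stacklevel=2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0   # a margin is empty: the proportions are identical
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


REPORT_COLUMNS = ("Accuracy", "Sensitivity", "Specificity", "Precision", "F1-Score")

_METRIC_FUNS = {
    "Accuracy": accuracy,
    "Sensitivity": macro_sensitivity,
    "Specificity": macro_specificity,
    "Precision": macro_precision,
    "F1-Score": macro_f1,
}


@dataclass
class EvalReport:
    """Per-fold metrics, their mean ± sample SD, and the pooled AUC."""

    per_fold: pd.DataFrame                 # columns: fold + REPORT_COLUMNS
    mean: dict[str, float]
    sd: dict[str, float]
    auc: Optional[AucResult] = None
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = {col: f"{self.mean[col]:.3f} ± {self.sd[col]:.3f}" for col in REPORT_COLUMNS}
        if self.auc is not None:
            rows["AUC (micro)"] = (f"{self.auc.micro:.3f} "
                                   f"(95% CI, {self.auc.ci_low:.3f}–{self.auc.ci_high:.3f})")
        return pd.DataFrame([rows])

    def to_csv(self, path: str) -> str:
        self.per_fold.to_csv(path, index=False)
        return path


def crossval_report(records, folds: int = 5, auc_bootstrap: int = 2000,
                    seed: int = 0, compute_auc: bool = True) -> EvalReport:
    """Aggregate prediction records over cross-validation folds.

    Per-fold confusion matrices give per-fold metrics, summarized as mean and
    sample SD (n−1) across folds; AUC is computed once on the pooled records.
    Accepts a list of PredictionRecords or a predictions.csv-schema DataFrame.
    """
    if isinstance(records, pd.DataFrame):
        from femursplit.harness import dataframe_to_records
        records = dataframe_to_records(records)
    fold_ids = sorted({r.fold_index for r in records})
    if len(fold_ids) > folds:
        raise ValueError(f"records carry {len(fold_ids)} fold indices, expected <= {folds}")
    caught: list[str] = []
    rows = []
    for k in fold_ids:
        sub = [r for r in records if r.fold_index == k]
        present = {r.true_label for r in sub}
        if len(sub) < len(present):
            caught.append(f"fold {k}: fewer samples than classes present")
        cm = ConfusionMatrix3.from_labels([r.true_label for r in sub],
                                          [r.predicted_label for r in sub])
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            row = {"fold": k}
            for col, fun in _METRIC_FUNS.items():
                row[col] = fun(cm)
        caught.extend(f"fold {k}: {w.message}" for w in wrec)
        rows.append(row)
    per_fold = pd.DataFrame(rows, columns=["fold", *REPORT_COLUMNS])
    mean = {c: float(per_fold[c].mean()) for c in REPORT_COLUMNS}
    sd = {c: (float(per_fold[c].std(ddof=1)) if len(per_fold) > 1 else 0.0)
          for c in REPORT_COLUMNS}
    auc = None
    if compute_auc and len({r.true_label for r in records}) >= 2:
        auc = micro_roc_auc(records, n_bootstrap=auc_bootstrap, seed=seed)
    return EvalReport(per_fold=per_fold, mean=mean, sd=sd, auc=auc, warnings_=caught)
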