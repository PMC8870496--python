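"""Evaluation metrics against independent brute-force oracles."""

import warnings

import numpy as np
import pytest
from scipy import stats

import femursplit.metrics as M
from femursplit.harness import PredictionRecord
from femursplit.images import LABELS

# ---------------------------------------------------------------- oracles


def oracle_per_class(true, pred, positive):
    """One-vs-rest TP/FP/FN/TN by direct enumeration over samples."""
    tp = sum(t == positive and p == positive for t, p in zip(true, pred))
    fp = sum(t != positive and p == positive for t, p in zip(true, pred))
    fn = sum(t == positive and p != positive for t, p in zip(true, pred))
    tn = len(true) - tp - fp - fn
    return tp, fp, fn, tn


def oracle_macro(true, pred, kind):
    vals = []
    for lab in LABELS:
        if lab not in true and lab not in pred:
            continue
        tp, fp, fn, tn = oracle_per_class(true, pred, lab)
        if kind == "precision":
            vals.append(tp / (tp + fp) if tp + fp else 0.0)
        elif kind == "sensitivity":
            vals.append(tp / (tp + fn) if tp + fn else 0.0)
        elif kind == "specificity":
            vals.append(tn / (tn + fp) if tn + fp else 0.0)
        elif kind == "f1":
            p = tp / (tp + fp) if tp + fp else 0.0
            s = tp / (tp + fn) if tp + fn else 0.0
            vals.append(2 * p * s / (p + s) if p + s else 0.0)
    return float(np.mean(vals))


def oracle_auc_mann_whitney(y_binary, scores):
    """AUC as the tie-corrected probability that a positive outranks a
    negative (Mann-Whitney identity), independent of any ROC integration."""
    pos = scores[y_binary == 1]
    neg = scores[y_binary == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def random_labelled_records(rng, n, informative=False):
    true = rng.choice(LABELS, size=n)
    raw = rng.random((n, 3))
    if informative:
        raw[np.arange(n), [LABELS.index(t) for t in true]] += rng.random(n)
    scores = raw / raw.sum(axis=1, keepdims=True)
    return [PredictionRecord(f"s{i}", true[i], LABELS[int(np.argmax(scores[i]))],
                             tuple(scores[i]), fold_index=1 + i % 5)
            for i in range(n)]


# ---------------------------------------------------------------- tests


class TestConfusionMatrix:
    def test_one_vs_rest_marginalization_matches_enumeration(self):
        rng = np.random.default_rng(0)
        true = rng.choice(LABELS, size=60)
        pred = rng.choice(LABELS, size=60)
        cm = M.ConfusionMatrix3.from_labels(true, pred)
        assert cm.d_test == 60
        for i, lab in enumerate(LABELS):
            assert cm.one_vs_rest(i) == oracle_per_class(true, pred, lab)

    def test_shape_and_sign_validation(self):
        with pytest.raises(ValueError):
            M.ConfusionMatrix3(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            M.ConfusionMatrix3(-np.ones((3, 3)))


class TestPointMetrics:
    def test_perfect_diagonal(self):
        cm = M.ConfusionMatrix3(np.diag([10, 10, 10]))
        for fun in (M.accuracy, M.macro_precision, M.macro_sensitivity,
                    M.macro_specificity, M.macro_f1):
            assert fun(cm) == 1.0

    def test_uniform_matrix_accuracy_is_one_third(self):
        assert M.accuracy(M.ConfusionMatrix3(np.ones((3, 3)))) == pytest.approx(1 / 3)

    def test_all_predicted_one_class_specificity(self):
        """Truth balanced, everything predicted no_tumor: that class has
        specificity 0, the others 1, macro 2/3."""
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = 5
        assert M.macro_specificity(M.ConfusionMatrix3(counts)) == pytest.approx(2 / 3)

    def test_macro_metrics_match_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(6, 40)
            true = rng.choice(LABELS, size=n)
            pred = rng.choice(LABELS, size=n)
            cm = M.ConfusionMatrix3.from_labels(true, pred)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert M.accuracy(cm) == pytest.approx(
                    np.mean(true == pred), abs=1e-12)
                assert M.macro_precision(cm) == pytest.approx(
                    oracle_macro(true, pred, "precision"), abs=1e-12)
                assert M.macro_sensitivity(cm) == pytest.approx(
                    oracle_macro(true, pred, "sensitivity"), abs=1e-12)
                assert M.macro_specificity(cm) == pytest.approx(
                    oracle_macro(true, pred, "specificity"), abs=1e-12)
                assert M.macro_f1(cm) == pytest.approx(
                    oracle_macro(true, pred, "f1"), abs=1e-12)

    def test_vacuous_class_is_skipped(self):
        """A class absent from truth and prediction drops out of the macro
        average rather than polluting it with zeros."""
        true = ["no_tumor", "no_tumor", "benign", "benign"]
        pred = ["no_tumor", "benign", "benign", "benign"]
        cm = M.ConfusionMatrix3.from_labels(true, pred)
        assert M.macro_sensitivity(cm) == pytest.approx((1 / 2 + 2 / 2) / 2)

    def test_zero_denominator_contributes_zero_with_warning(self):
        true = ["no_tumor", "benign", "malignant"]
        pred = ["no_tumor", "no_tumor", "no_tumor"]
        cm = M.ConfusionMatrix3.from_labels(true, pred)
        with pytest.warns(UserWarning, match="precision undefined"):
            val = M.macro_precision(cm)
        assert val == pytest.approx((1 / 3 + 0 + 0) / 3)

    def test_binary_collapse_recovers_standard_definitions(self):
        """With one class absent, macro sensitivity/specificity reduce to the
        mean of the two binary recalls (each class's recall is the other's
        specificity)."""
        rng = np.random.default_rng(2)
        true = rng.choice(LABELS[:2], size=50)
        pred = rng.choice(LABELS[:2], size=50)
        cm = M.ConfusionMatrix3.from_labels(true, pred)
        recalls = []
        for lab in LABELS[:2]:
            tp, fp, fn, tn = oracle_per_class(true, pred, lab)
            recalls.append(tp / (tp + fn))
        assert M.macro_sensitivity(cm) == pytest.approx(np.mean(recalls))
        assert M.macro_specificity(cm) == pytest.approx(np.mean(recalls[::-1]))


class TestAuc:
    def test_perfectly_ranked_scores_reach_one(self):
        rng = np.random.default_rng(3)
        recs = random_labelled_records(rng, 30)
        perfect = [PredictionRecord(r.femur_id, r.true_label, r.true_label,
                                    tuple(0.8 if lab == r.true_label else 0.1
                                          for lab in LABELS))
                   for r in recs]
        res = M.micro_roc_auc(perfect, n_bootstrap=50, seed=0)
        assert res.micro == 1.0 and res.macro == 1.0

    def test_micro_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            recs = random_labelled_records(rng, int(rng.integers(10, 40)))
            y = np.array([[lab == r.true_label for lab in LABELS] for r in recs],
                         dtype=int).ravel()
            s = np.array([r.class_scores for r in recs]).ravel()
            res = M.micro_roc_auc(recs, n_bootstrap=0, seed=0)
            assert res.micro == pytest.approx(oracle_auc_mann_whitney(y, s), abs=1e-12)

    def test_uninformative_scores_hover_near_half(self):
        rng = np.random.default_rng(5)
        recs = random_labelled_records(rng, 2000)
        res = M.micro_roc_auc(recs, n_bootstrap=0, seed=0)
        assert abs(res.micro - 0.5) < 3 / np.sqrt(2000)

    def test_invariance_under_monotone_score_transform(self):
        """A strictly increasing affine map of every pooled score (chosen so
        each record still sums to 1) leaves both AUC averages unchanged."""
        rng = np.random.default_rng(6)
        recs = random_labelled_records(rng, 40, informative=True)
        warped = [PredictionRecord(r.femur_id, r.true_label, r.predicted_label,
                                   tuple(0.5 * s + 1 / 6 for s in r.class_scores))
                  for r in recs]
        a = M.micro_roc_auc(recs, n_bootstrap=0, seed=0)
        b = M.micro_roc_auc(warped, n_bootstrap=0, seed=0)
        assert b.micro == pytest.approx(a.micro, abs=1e-12)
        assert b.macro == pytest.approx(a.macro, abs=1e-12)

    def test_bootstrap_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(7)
        recs = random_labelled_records(rng, 120, informative=True)
        res = M.micro_roc_auc(recs, n_bootstrap=300, seed=1)
        assert res.ci_low <= res.micro <= res.ci_high
        assert M.micro_roc_auc(recs, n_bootstrap=300, seed=1).ci_low == res.ci_low

    def test_single_class_truth_rejected(self):
        recs = [PredictionRecord("a", "benign", "benign", (0.1, 0.8, 0.1)),
                PredictionRecord("b", "benign", "benign", (0.2, 0.6, 0.2))]
        with pytest.raises(ValueError, match="2 distinct"):
            M.micro_roc_auc(recs)


class TestChiSquared:
    def test_identical_proportions_give_zero(self):
        chi2, p = M.chi2_accuracy_compare(50, 100, 50, 100)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        chi2, p = M.chi2_accuracy_compare(90, 100, 70, 100)
        assert chi2 == pytest.approx(12.5)
        assert p == pytest.approx(0.000407, abs=5e-6)

    def test_symmetry_in_raters(self):
        a = M.chi2_accuracy_compare(83, 97, 61, 88)
        b = M.chi2_accuracy_compare(61, 88, 83, 97)
        assert a == b

    def test_closed_form_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_a, n_b = rng.integers(10, 200, size=2)
            ca, cb = rng.integers(1, n_a), rng.integers(1, n_b)
            chi2, p = M.chi2_accuracy_compare(int(ca), int(n_a), int(cb), int(n_b))
            ref = stats.chi2_contingency(
                [[ca, n_a - ca], [cb, n_b - cb]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_expected_cell_warns(self):
        with pytest.warns(UserWarning, match="expected cell"):
            M.chi2_accuracy_compare(1, 2, 2, 2)


class TestCrossvalReport:
    def test_identical_folds_have_zero_sd(self):
        rng = np.random.default_rng(9)
        base = random_labelled_records(rng, 20)
        recs = []
        for k in range(1, 6):
            for r in base:
                recs.append(PredictionRecord(r.femur_id, r.true_label,
                                             r.predicted_label, r.class_scores,
                                             fold_index=k))
        rep = M.crossval_report(recs, folds=5, auc_bootstrap=0)
        for col in M.REPORT_COLUMNS:
            assert rep.sd[col] == pytest.approx(0.0, abs=1e-12)

    def test_per_fold_accuracy_matches_recount(self):
        rng = np.random.default_rng(10)
        recs = random_labelled_records(rng, 100)
        rep = M.crossval_report(recs, folds=5, auc_bootstrap=0)
        for k in rep.per_fold["fold"]:
            sub = [r for r in recs if r.fold_index == k]
            want = np.mean([r.true_label == r.predicted_label for r in sub])
            got = float(rep.per_fold.loc[rep.per_fold["fold"] == k, "Accuracy"].iloc[0])
            assert got == pytest.approx(want, abs=1e-12)

    def test_report_columns_match_published_table_layout(self):
        rng = np.random.default_rng(11)
        rep = M.crossval_report(random_labelled_records(rng, 50), auc_bootstrap=0)
        assert tuple(rep.per_fold.columns[1:]) == \
            ("Accuracy", "Sensitivity", "Specificity", "Precision", "F1-Score")
        assert set(rep.summary().columns) >= set(M.REPORT_COLUMNS)
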