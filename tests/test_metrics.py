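"""Confusion-matrix statistics, binomial CIs and the validation protocols."""

import numpy as np
import pytest
from scipy.special import gammaln

from accelhar.metrics import (
    ConfusionMatrix,
    accuracy,
    binomial_ci,
    cross_context,
    format_percent,
    kfold_cv,
    macro_precision,
    macro_recall,
    merge_classes,
    per_class_precision,
    per_class_recall,
)
from accelhar.classifiers import ClassifierSpec
from accelhar.signal_io import ACTIVITIES
from conftest import embed_features


def random_cm(rng, k=6, high=60):
    return ConfusionMatrix(rng.integers(0, high, size=(k, k)), ACTIVITIES[:k])


def clopper_pearson_bisection(correct, total, level=0.95):
    """Independent oracle: bisect the binomial tail probabilities computed
    by log-space pmf summation (no beta quantiles involved)."""
    alpha = 1.0 - level

    def log_pmf(k, n, p):
        if p in (0.0, 1.0):
            return 0.0 if (p == 0.0) == (k == 0) or (p == 1.0) == (k == n) else -np.inf
        return (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p)
        )

    def tail_ge(p):  # P(X >= correct)
        ks = np.arange(correct, total + 1)
        return np.exp([log_pmf(k, total, p) for k in ks]).sum()

    def tail_le(p):  # P(X <= correct)
        ks = np.arange(0, correct + 1)
        return np.exp([log_pmf(k, total, p) for k in ks]).sum()

    def bisect(f, target, lo, hi, increasing):
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lower = 0.0 if correct == 0 else bisect(tail_ge, alpha / 2, 0.0, 1.0, True)
    upper = 1.0 if correct == total else bisect(tail_le, alpha / 2, 0.0, 1.0, False)
    return lower, upper


class TestAccuracy:
    def test_stated_denominator_reproduces_printed_percentages(self):
        diag = np.diag([191, 148, 135, 239, 259, 100])
        cm = ConfusionMatrix(diag, ACTIVITIES)
        assert format_percent(accuracy(cm, total_override=1170)) == "91.6%"
        cm4 = ConfusionMatrix(np.diag([327, 99, 66, 116, 161, 166]), ACTIVITIES)
        assert format_percent(accuracy(cm4, total_override=1089)) == "85.9%"

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int), ACTIVITIES)
        assert accuracy(cm) == 1.0
        assert np.all(per_class_recall(cm) == 1.0)
        assert np.all(per_class_precision(cm) == 1.0)

    def test_zero_total_rejected(self):
        cm = ConfusionMatrix(np.zeros((6, 6), dtype=int), ACTIVITIES)
        with pytest.raises(ValueError):
            accuracy(cm)

    def test_weighted_recall_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            cm = random_cm(rng)
            support = cm.counts.sum(axis=1)
            r = per_class_recall(cm)
            expected = np.nansum(support * np.where(np.isnan(r), 0.0, r)) / cm.total
            assert accuracy(cm) == pytest.approx(expected, rel=1e-12)


class TestPerClassMetrics:
    def test_macro_matches_per_row_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cm = random_cm(rng)
            recalls, precisions = [], []
            for i in range(6):
                row = cm.counts[i].sum()
                col = cm.counts[:, i].sum()
                if row:
                    recalls.append(cm.counts[i, i] / row)
                if col:
                    precisions.append(cm.counts[i, i] / col)
            assert macro_recall(cm) == pytest.approx(np.mean(recalls))
            assert macro_precision(cm) == pytest.approx(np.mean(precisions))

    def test_zero_support_class_is_undefined_and_excluded(self):
        counts = np.eye(6, dtype=int) * 5
        counts[2, :] = 0  # 'sit' never occurs
        cm = ConfusionMatrix(counts, ACTIVITIES)
        assert np.isnan(per_class_recall(cm)[2])
        assert macro_recall(cm) == pytest.approx(1.0)


class TestBinomialCI:
    def test_zero_successes_lower_bound_is_zero(self):
        ci = binomial_ci(0, 10, method="clopper_pearson")
        assert ci.lower == 0.0

    def test_wald_closed_form(self):
        ci = binomial_ci(5, 10, method="normal")
        half = 1.959963985 * np.sqrt(0.025)
        assert ci.lower == pytest.approx(0.5 - half, abs=1e-3)
        assert ci.upper == pytest.approx(0.5 + half, abs=1e-3)

    @pytest.mark.parametrize(
        "correct,total", [(1072, 1170), (595, 1089), (3, 17), (17, 17), (0, 8)]
    )
    def test_clopper_pearson_matches_bisection_oracle(self, correct, total):
        ci = binomial_ci(correct, total, method="clopper_pearson")
        lo, hi = clopper_pearson_bisection(correct, total)
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(hi, abs=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(11, 10)


class TestMergeClasses:
    def test_merge_all_into_one(self):
        rng = np.random.default_rng(2)
        cm = random_cm(rng)
        merged = merge_classes(cm, [list(ACTIVITIES)])
        assert merged.counts.shape == (1, 1)
        assert merged.total == cm.total
        assert accuracy(merged) == 1.0

    def test_singleton_partition_is_identity(self):
        rng = np.random.default_rng(3)
        cm = random_cm(rng)
        merged = merge_classes(cm, [[c] for c in ACTIVITIES])
        assert np.array_equal(merged.counts, cm.counts)
        assert merged.classes == cm.classes

    def test_non_partition_rejected(self):
        cm = random_cm(np.random.default_rng(4))
        with pytest.raises(ValueError, match="partition"):
            merge_classes(cm, [["walk", "stairs"], ["lie"]])

    def test_merging_never_decreases_accuracy(self):
        # recount oracle: merged accuracy = (diagonal + walk/stairs
        # confusion) / total, and is never below the unmerged accuracy
        rng = np.random.default_rng(5)
        groups = [["lie"], ["stand"], ["sit"], ["wheel"], ["walk", "stairs"]]
        iw, is_ = ACTIVITIES.index("walk"), ACTIVITIES.index("stairs")
        for _ in range(1000):
            cm = random_cm(rng)
            if cm.total == 0:
                continue
            merged = merge_classes(cm, groups)
            expected = (
                np.trace(cm.counts) + cm.counts[iw, is_] + cm.counts[is_, iw]
            ) / cm.total
            assert accuracy(merged) == pytest.approx(expected, rel=1e-12)
            assert accuracy(merged) >= accuracy(cm)


class TestProtocols:
    def _one_hot_dataset(self, n_per_class=12, classes=ACTIVITIES):
        labels = [c for c in classes for _ in range(n_per_class)]
        block = np.array([[1.0 if classes[j] == c else 0.0 for j in range(len(classes))] for c in labels])
        return embed_features(block, labels)

    def test_perfectly_informative_features_give_diagonal_matrix(self):
        data = self._one_hot_dataset()
        cm = kfold_cv(data, ClassifierSpec(kind="decision_tree", min_split=2), folds=4, seed=0)
        assert np.array_equal(cm.counts, np.diag(cm.counts.sum(axis=1)))

    def test_every_clip_predicted_exactly_once(self):
        data = self._one_hot_dataset(n_per_class=10)
        for seed in (0, 1, 2):
            cm = kfold_cv(data, ClassifierSpec(kind="knn"), folds=5, seed=seed)
            assert cm.total == len(data)

    def test_kfold_deterministic_in_seed(self, tiny_datasets):
        lab, _ = tiny_datasets
        spec = ClassifierSpec(kind="naive_bayes")
        a = kfold_cv(lab, spec, folds=4, seed=9)
        b = kfold_cv(lab, spec, folds=4, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_rare_class_rejected(self):
        data = self._one_hot_dataset(n_per_class=3)
        with pytest.raises(ValueError, match="fewer rows"):
            kfold_cv(data, ClassifierSpec(kind="knn"), folds=5, seed=0)

    def test_cross_context_warns_on_shared_context_tags(self):
        data = self._one_hot_dataset()
        with pytest.warns(UserWarning, match="context"):
            cross_context(data, data, ClassifierSpec(kind="naive_bayes"))

    def test_resubstitution_bound(self, tiny_datasets):
        lab, _ = tiny_datasets
        spec = ClassifierSpec(kind="svm", seed=0)
        with pytest.warns(UserWarning):
            resub = accuracy(cross_context(lab, lab, spec))
        cv = accuracy(kfold_cv(lab, spec, folds=4, seed=0))
        assert resub >= cv - 1e-12
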