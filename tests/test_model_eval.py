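"""Splitting, cross-entropy, head training, confusion metrics, AUC, ANOVA."""

import numpy as np
import pytest
from scipy import stats

from dermpipe.exceptions import DegenerateInputError, DomainError
from dermpipe.model_eval import (
    ClassifierHead,
    TrainConfig,
    anova_oneway,
    auc_ovr,
    confusion_matrix,
    cross_entropy,
    metrics_from_confusion,
    split_dataset,
    train_head,
)


class TestSplitDataset:
    def test_70_20_10_on_single_class(self):
        labels = np.zeros(100, dtype=int)
        tr, te, va = split_dataset(labels, (0.7, 0.2, 0.1), seed=0)
        assert (len(tr), len(te), len(va)) == (70, 20, 10)

    def test_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=123)
        tr, te, va = split_dataset(labels, seed=1)
        allidx = np.concatenate([tr, te, va])
        assert len(allidx) == 123 and len(np.unique(allidx)) == 123

    def test_stratified_within_one_sample(self):
        labels = np.array([0] * 50 + [1] * 30 + [2] * 20)
        tr, te, va = split_dataset(labels, seed=2)
        for c, n in ((0, 50), (1, 30), (2, 20)):
            assert abs((labels[tr] == c).sum() - 0.7 * n) <= 1
            assert abs((labels[te] == c).sum() - 0.2 * n) <= 1
            assert abs((labels[va] == c).sum() - 0.1 * n) <= 1

    def test_same_seed_identical(self):
        labels = np.random.default_rng(1).integers(0, 3, size=60)
        a = split_dataset(labels, seed=5)
        b = split_dataset(labels, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_tiny_class_rejected(self):
        with pytest.raises(DomainError):
            split_dataset(np.array([0, 0, 0, 1, 1]), seed=0)


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        probs = np.eye(8)[[0, 3, 7]]
        assert cross_entropy(probs, [0, 3, 7]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_eight_way_is_ln8(self):
        probs = np.full((5, 8), 1 / 8)
        assert cross_entropy(probs, [0, 1, 2, 3, 4]) == pytest.approx(np.log(8))

    def test_hand_built_two_sample_case(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3]])
        expected = -(np.log(0.7) + np.log(0.3)) / 2
        assert cross_entropy(probs, [0, 2]) == pytest.approx(expected)

    def test_invalid_rows_rejected(self):
        with pytest.raises(DomainError):
            cross_entropy(np.array([[0.5, 0.2]]), [0])


class TestTrainHead:
    def test_separable_four_class_reaches_full_accuracy(self):
        # 80 standardized, linearly separable samples; small batches so the
        # fixed 0.001 RMSprop step makes enough updates within 40 epochs
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(2.0 * c - 3.0, 0.5, (20, 6)) for c in range(4)])
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = np.repeat(np.arange(4), 20)
        head = ClassifierHead(n_features=6, n_classes=4, hidden=32, seed=1)
        record = train_head(head, X, y, TrainConfig(epochs=40, batch_size=4, hidden=32, seed=2))
        assert (head.predict(X) == y).mean() == 1.0
        assert np.isfinite(record.cross_entropy).all()
        assert len(record.cross_entropy) == 40

    def test_loss_decreases(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(3, 1, (30, 4))])
        y = np.repeat([0, 1], 30)
        head = ClassifierHead(4, 2, hidden=16, seed=0)
        record = train_head(head, X, y, TrainConfig(epochs=20, hidden=16, seed=0))
        assert record.cross_entropy[-1] < record.cross_entropy[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 3, size=40)
        heads = []
        for _ in range(2):
            h = ClassifierHead(5, 3, hidden=8, seed=7)
            train_head(h, X, y, TrainConfig(epochs=5, hidden=8, seed=7))
            heads.append(h)
        assert np.array_equal(heads[0].w1, heads[1].w1)
        assert np.array_equal(heads[0].w2, heads[1].w2)

    def test_width_mismatch_rejected(self):
        head = ClassifierHead(5, 3)
        with pytest.raises(DomainError):
            train_head(head, np.zeros((4, 7)), np.zeros(4, dtype=int))


class TestConfusionAndMetrics:
    def test_perfect_predictions_diagonal(self):
        y = np.arange(8)
        c = confusion_matrix(y, y)
        assert np.array_equal(c, np.eye(8, dtype=int))

    def test_hand_built_six_sample_case(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 0, 2]
        c = confusion_matrix(y_true, y_pred, n_classes=3)
        expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 1]])
        assert np.array_equal(c, expected)

    def test_all_one_class_predictions_single_column(self):
        c = confusion_matrix([0, 1, 2, 3], [2, 2, 2, 2], n_classes=4)
        assert c[:, 2].sum() == 4 and c.sum() == 4

    def test_out_of_range_label_rejected(self):
        with pytest.raises(DomainError):
            confusion_matrix([0, 9], [0, 1], n_classes=8)

    def test_binary_toy_metric_values(self):
        # TP=50, FP=10, FN=10, TN=30 for class 1
        c = np.array([[30, 10], [10, 50]])
        rep = metrics_from_confusion(c)
        assert rep.per_class["acc"][1] == pytest.approx(0.8)
        assert rep.per_class["prec"][1] == pytest.approx(50 / 60, abs=1e-4)
        assert rep.per_class["rec"][1] == pytest.approx(50 / 60, abs=1e-4)
        assert rep.per_class["f1"][1] == pytest.approx(50 / 60, abs=1e-4)

    def test_perfect_classifier_all_ones(self):
        rep = metrics_from_confusion(np.diag([5, 7, 9]))
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0 and rep.macro_precision == 1.0

    def test_f1_harmonic_identity(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 20, (6, 6))
        rep = metrics_from_confusion(c)
        p, r, f = rep.per_class["prec"], rep.per_class["rec"], rep.per_class["f1"]
        ok = (p + r) > 0
        assert np.allclose(f[ok], 2 * p[ok] * r[ok] / (p[ok] + r[ok]))

    def test_matches_per_sample_brute_force(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        rep = metrics_from_confusion(confusion_matrix(y_true, y_pred, 4))
        for c in range(4):
            tp = np.sum((y_true == c) & (y_pred == c))
            fp = np.sum((y_true != c) & (y_pred == c))
            fn = np.sum((y_true == c) & (y_pred != c))
            tn = np.sum((y_true != c) & (y_pred != c))
            assert rep.per_class["acc"][c] == pytest.approx((tp + tn) / 200)
            if tp + fp:
                assert rep.per_class["prec"][c] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert rep.per_class["rec"][c] == pytest.approx(tp / (tp + fn))

    def test_zero_denominator_flagged(self):
        c = np.array([[5, 0], [0, 0]])  # class 1 absent and never predicted
        rep = metrics_from_confusion(c)
        assert 1 in rep.degenerate_classes
        assert rep.per_class["prec"][1] == 0.0


class TestAUC:
    def test_perfect_separation_is_one(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert auc_ovr(y, probs) == pytest.approx(1.0)

    def test_inverted_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.8, 0.2], [0.9, 0.1]])
        assert auc_ovr(y, probs) == pytest.approx(0.0)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 10)
        s = rng.uniform(size=10)
        probs = np.column_stack([1 - s, s])
        pos, neg = s[y == 1], s[y == 0]
        pairs = [(0.5 if p == n else float(p > n)) for p in pos for n in neg]
        oracle_auc1 = np.mean(pairs)
        # with complementary binary scores both one-vs-rest AUCs coincide
        assert auc_ovr(y, probs) == pytest.approx(oracle_auc1)

    def test_absent_class_excluded(self):
        y = np.array([0, 0, 1, 1])
        probs = np.column_stack([[0.8, 0.7, 0.2, 0.1], [0.2, 0.3, 0.8, 0.9], [0.0, 0.0, 0.0, 0.0]])
        probs = probs / probs.sum(axis=1, keepdims=True)
        assert 0.0 <= auc_ovr(y, probs) <= 1.0


class TestAnova:
    def test_equal_means_give_near_zero_f(self):
        rng = np.random.default_rng(0)
        groups = [5 + rng.normal(0, 1, 50) for _ in range(3)]
        f, p = anova_oneway(groups)
        assert f < 2.0 and p > 0.05

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        f, _ = anova_oneway([a, b])
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)

    def test_hand_computed_two_by_three_example(self):
        # groups {1,2,3} and {2,3,4}: SSB=1.5 (df 1), SSW=4 (df 4) -> F=1.5
        f, p = anova_oneway([np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])])
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(stats.f.sf(1.5, 1, 4))

    def test_zero_within_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])

    def test_too_few_groups_rejected(self):
        with pytest.raises(DomainError):
            anova_oneway([np.array([1.0, 2.0])])
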