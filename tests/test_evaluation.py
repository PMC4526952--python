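"""Folds, accuracy metrics, ROC/AUC (dual-route), break-even."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from tweetmine.evaluation import (
    auc,
    break_even,
    cross_validate,
    multiclass_accuracy,
    roc_points,
    stratified_folds,
    topk_accuracy,
    trapezoid_auc,
)


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        labels = ["A"] * 10 + ["B"] * 10
        fa = stratified_folds(labels, k=10, seed=0)
        for fold in range(10):
            te = fa.test_indices(fold)
            assert len(te) == 2
            assert sorted(labels[i] for i in te) == ["A", "B"]

    def test_small_class_spreads_over_seven_folds(self):
        labels = ["A"] * 50 + ["rare"] * 7
        fa = stratified_folds(labels, k=10, seed=1)
        folds_with_rare = {
            fold for fold in range(10)
            if any(labels[i] == "rare" for i in fa.test_indices(fold))
        }
        assert len(folds_with_rare) == 7

    def test_seed_contract(self):
        labels = ["A", "B"] * 20
        assert stratified_folds(labels, 5, seed=3) == stratified_folds(labels, 5, seed=3)

    def test_per_class_balance_within_one(self, rng):
        labels = list(rng.choice(["A", "B", "C"], size=83))
        fa = stratified_folds(labels, k=10, seed=4)
        for cls in "ABC":
            counts = [
                sum(labels[i] == cls for i in fa.test_indices(f)) for f in range(10)
            ]
            assert max(counts) - min(counts) <= 1

    def test_k_exceeding_items_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_folds(["A", "B"], k=10, seed=0)


class TestAccuracies:
    def test_pooled_ratio(self):
        pred = ["x"] * 293 + ["y"] * 123
        truth = ["x"] * 293 + ["z"] * 123
        assert multiclass_accuracy(pred, truth) == pytest.approx(293 / 416)

    def test_identical_and_disjoint(self):
        assert multiclass_accuracy(["a", "b"], ["a", "b"]) == 1.0
        assert multiclass_accuracy(["a", "b"], ["b", "a"]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            multiclass_accuracy(["a"], ["a", "b"])

    def test_topk_all_categories_is_one(self, rng):
        scores = rng.random((20, 4))
        truth = rng.integers(0, 4, size=20)
        assert topk_accuracy(scores, truth, k=4) == 1.0

    def test_top2_ratio(self, rng):
        # construct 246 items with exactly 158 top-2 hits
        n, hits = 246, 158
        scores = np.zeros((n, 9))
        truth = np.full(n, 4)
        scores[:, 0] = 0.5  # argmax is class 0 everywhere
        scores[:hits, 4] = 0.4  # true class ranks second for the hits
        scores[hits:, 1] = 0.4
        assert topk_accuracy(scores, truth, k=2) == pytest.approx(158 / 246)

    def test_top1_equals_argmax_accuracy(self, rng):
        scores = rng.random((50, 3))
        truth = rng.integers(0, 3, size=50)
        pred = np.argmax(scores, axis=1)
        assert topk_accuracy(scores, truth, k=1) == pytest.approx(
            multiclass_accuracy(list(pred), list(truth))
        )

    def test_tie_break_by_category_order(self):
        scores = np.array([[0.5, 0.5, 0.0]])
        assert topk_accuracy(scores, [0], k=1) == 1.0
        assert topk_accuracy(scores, [1], k=1) == 0.0


class TestRocAuc:
    def test_perfect_separation_point(self):
        pts = roc_points([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert ((pts["recall"] == 1) & (pts["fall_out"] == 0)).any()

    def test_all_scores_equal(self):
        pts = roc_points([0.5] * 4, [True, False, True, False])
        # all-negative endpoint plus the single all-positive point
        assert len(pts) == 2
        assert pts.iloc[-1]["recall"] == 1.0 and pts.iloc[-1]["fall_out"] == 1.0
        assert auc([0.5] * 4, [True, False, True, False]) == 0.5

    def test_hand_enumerated_sweep(self):
        pts = roc_points([0.9, 0.4, 0.5, 0.1], [True, True, False, False])
        pairs = list(zip(pts["recall"], pts["fall_out"]))
        assert pairs == [(0.0, 0.0), (0.5, 0.0), (0.5, 0.5), (1.0, 0.5), (1.0, 1.0)]

    def test_brute_force_pairs(self):
        assert auc([0.9, 0.4, 0.5, 0.1], [True, True, False, False]) == 0.75

    def test_perfect_auc(self):
        assert auc([0.9, 0.8, 0.2], [True, True, False]) == 1.0

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.5, 0.6], [True, True])

    def test_dual_route_and_sklearn(self, rng):
        """Mann-Whitney AUC == trapezoid of the swept ROC == sklearn, on
        random instances including ties."""
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 6, size=n) / 5.0  # coarse grid forces ties
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            a = auc(scores, truth)
            assert a == pytest.approx(trapezoid_auc(scores, truth), abs=1e-9)
            assert a == pytest.approx(roc_auc_score(truth, scores), abs=1e-9)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(2000)
        truth = rng.random(2000) < 0.5
        assert abs(auc(scores, truth) - 0.5) < 0.03

    def test_recall_fallout_monotone_in_threshold(self, rng):
        scores = rng.random(50)
        truth = rng.random(50) < 0.5
        pts = roc_points(scores, truth)
        assert (np.diff(pts["recall"]) >= 0).all()
        assert (np.diff(pts["fall_out"]) >= 0).all()


class TestBreakEven:
    def test_perfect_classifier(self):
        assert break_even([0.9, 0.8, 0.1], [True, True, False]) == 100.0

    def test_hand_sweep_crossing(self):
        assert break_even([0.9, 0.6, 0.7, 0.2], [True, True, False, False]) == 50.0

    def test_single_top_positive(self):
        assert break_even([0.9, 0.1, 0.2], [True, False, False]) == 100.0

    def test_no_positives_error(self):
        with pytest.raises(ValueError, match="positive"):
            break_even([0.5, 0.4], [False, False])

    def test_interpolated_value_between_adjacent_points(self, rng):
        scores = rng.random(40)
        truth = rng.random(40) < 0.3
        if truth.any() and not truth.all():
            be = break_even(scores, truth)
            assert 0.0 <= be <= 100.0


class _StubPerfect:
    def __init__(self, n_cats):
        self.n = n_cats

    def fit(self, X, y):
        self.X, self.y = X.copy(), y.copy()
        return self

    def predict_scores(self, X):
        # nearest-neighbour lookup: perfect on the training distribution when
        # feature vectors are class-unique
        out = np.full((X.shape[0], self.n), (1 - 0.91) / (self.n - 1))
        for i, row in enumerate(X):
            j = int(np.argmin(((self.X - row) ** 2).sum(axis=1)))
            out[i] = (1 - 0.91) / (self.n - 1)
            out[i, self.y[j]] = 0.91
        return out


class _StubMajority:
    def fit(self, X, y):
        counts = np.bincount(y, minlength=9)
        self.major = int(np.argmax(counts))
        return self

    def predict_scores(self, X):
        out = np.full((X.shape[0], 9), 0.01)
        out[:, self.major] = 0.92
        return out


class TestCrossValidate:
    def test_perfect_stub_gives_accuracy_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, size=60)
        X = np.eye(3)[y]  # class-unique rows
        cats = ("A", "B", "C")
        folds = stratified_folds([cats[i] for i in y], k=5, seed=1)
        rep = cross_validate(X, [cats[i] for i in y], lambda: _StubPerfect(3),
                             folds, cats)
        assert rep.accuracy == 1.0
        assert rep.confusion.to_numpy().sum() == 60

    def test_majority_stub_matches_class_share(self):
        # class counts mirroring the labeled antibiotic set: majority 132/417
        counts = (21, 88, 28, 38, 72, 132, 16, 15, 7)
        cats = tuple(f"c{i}" for i in range(9))
        y = [cats[i] for i, c in enumerate(counts) for _ in range(c)]
        X = np.zeros((len(y), 3))
        folds = stratified_folds(y, k=10, seed=2)
        rep = cross_validate(X, y, _StubMajority, folds, cats)
        assert rep.accuracy == pytest.approx(132 / 417)

    def test_confusion_row_sums_are_class_counts(self):
        y = ["A"] * 12 + ["B"] * 8
        X = np.eye(2)[[0] * 12 + [1] * 8]
        folds = stratified_folds(y, k=4, seed=3)
        rep = cross_validate(X, y, lambda: _StubPerfect(2), folds, ("A", "B"))
        assert rep.confusion.sum(axis=1).tolist() == [12, 8]
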