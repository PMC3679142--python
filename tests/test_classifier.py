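"""Class-weighted SVM, P/R/F metrics, cross-validation and contributions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

import hetdimer as hd
from hetdimer.classifier import TrainedModel, select_best


def linear_gram(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    return x @ x.T, x


@pytest.fixture
def separable_toy():
    """1-D toy: positives at +2, negatives at -2; max margin is analytic."""
    points = np.array([2.0, 2.0, -2.0, -2.0])
    labels = np.array([1, 1, -1, -1])
    gram, x = linear_gram(points)
    return gram, x, labels


class TestFit:
    def test_separable_toy_has_zero_training_errors(self, separable_toy):
        gram, _, labels = separable_toy
        model = hd.fit(gram, labels, hd.TrainingConfig(1.0, 1.0))
        np.testing.assert_array_equal(hd.predict(model, gram), labels)

    def test_single_class_rejected(self):
        gram = np.eye(3)
        with pytest.raises(ValueError):
            hd.fit(gram, [1, 1, 1], hd.TrainingConfig())

    def test_asymmetric_gram_rejected(self):
        gram = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError):
            hd.fit(gram, [1, -1], hd.TrainingConfig())

    def test_equal_penalties_match_plain_svc(self):
        """C+ = C- reproduces the unweighted C-SVC decision function."""
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(2, 1, (10, 3)), rng.normal(-2, 1, (10, 3))])
        y = np.array([1] * 10 + [-1] * 10)
        gram = x @ x.T
        model = hd.fit(gram, y, hd.TrainingConfig(c_plus=1.0, c_minus=1.0))
        plain = SVC(kernel="precomputed", C=1.0).fit(gram, y)
        np.testing.assert_allclose(
            model.decision_values(gram), plain.decision_function(gram), atol=1e-8
        )

    def test_dual_coefficients_within_class_boxes(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0.5, 1, (15, 2)), rng.normal(-0.5, 1, (15, 2))])
        y = np.array([1] * 15 + [-1] * 15)
        config = hd.TrainingConfig(c_plus=2.0, c_minus=0.5)
        model = hd.fit(x @ x.T, y, config)
        for idx, coef in zip(model.support, model.dual_signed):
            bound = config.c_plus if y[idx] == 1 else config.c_minus
            assert 0 < abs(coef) <= bound + 1e-9
            assert np.sign(coef) == y[idx]


class TestPredict:
    def test_tie_at_zero_is_positive(self):
        model = TrainedModel(support=np.array([], dtype=int), dual_signed=np.array([]),
                             bias=0.0, n_train=3, config=hd.TrainingConfig())
        np.testing.assert_array_equal(hd.predict(model, np.zeros((2, 3))), [1, 1])

    def test_empty_test_set(self, separable_toy):
        gram, _, labels = separable_toy
        model = hd.fit(gram, labels, hd.TrainingConfig())
        assert hd.predict(model, np.empty((0, 4))).size == 0

    def test_column_mismatch_rejected(self, separable_toy):
        gram, _, labels = separable_toy
        model = hd.fit(gram, labels, hd.TrainingConfig())
        with pytest.raises(ValueError):
            hd.predict(model, np.zeros((1, 5)))


class TestPrecisionRecallF:
    def test_worked_confusion(self):
        predicted = np.array([1, 1, 1, -1, -1, -1])
        truth = np.array([1, 1, -1, 1, 1, -1])  # TP=2 FP=1 FN=2
        prf = hd.precision_recall_f(predicted, truth)
        assert prf.precision == pytest.approx(2 / 3)
        assert prf.recall == pytest.approx(0.5)
        assert prf.fmeasure == pytest.approx(4 / 7)

    def test_perfect_prediction(self):
        prf = hd.precision_recall_f([1, -1, 1], [1, -1, 1])
        assert (prf.precision, prf.recall, prf.fmeasure) == (1.0, 1.0, 1.0)

    def test_no_predicted_positives(self):
        prf = hd.precision_recall_f([-1] * 5, [1] * 5)
        assert (prf.precision, prf.recall, prf.fmeasure) == (0.0, 0.0, 0.0)
        assert prf.fn == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hd.precision_recall_f([1], [1, -1])

    def test_matches_brute_force_counts_and_harmonic_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            predicted = rng.choice([1, -1], size=n)
            truth = rng.choice([1, -1], size=n)
            prf = hd.precision_recall_f(predicted, truth)
            tp = sum(1 for p, t in zip(predicted, truth) if p == t == 1)
            fp = sum(1 for p, t in zip(predicted, truth) if p == 1 and t == -1)
            fn = sum(1 for p, t in zip(predicted, truth) if p == -1 and t == 1)
            assert (prf.tp, prf.fp, prf.fn) == (tp, fp, fn)
            if prf.precision + prf.recall > 0:
                assert prf.fmeasure == pytest.approx(
                    2 * prf.precision * prf.recall / (prf.precision + prf.recall)
                )
            else:
                assert prf.fmeasure == 0.0


class TestCrossValidate:
    def test_deterministic_given_seed(self, default_features):
        features, labels, indicator = default_features
        config = hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=0.6))
        cv = hd.CVConfig(10, seed=123)
        first = hd.cross_validate(features, labels, indicator, config, cv)
        second = hd.cross_validate(features, labels, indicator, config, cv)
        assert first == second

    def test_fold_metrics_bound_the_average(self, default_features):
        features, labels, indicator = default_features
        config = hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=0.6))
        result = hd.cross_validate(features, labels, indicator, config, hd.CVConfig(10, 0))
        fold_f = [f.fmeasure for f in result.folds]
        assert all(0.0 <= f <= 1.0 for f in fold_f)
        assert min(fold_f) <= result.fmeasure <= max(fold_f)
        assert result.fmeasure == pytest.approx(np.mean(fold_f))

    def test_leave_one_out_partitions_exactly(self):
        """k = n folds on a 6-example toy: every example is tested exactly
        once and the split is reproducible from the seed."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 2))
        x[:3] += 3.0
        labels = np.array([1, 1, 1, -1, -1, -1])
        indicator = np.eye(6)
        config = hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=0.0))
        cv = hd.CVConfig(n_folds=6, seed=9, stratified=False)
        result = hd.cross_validate(x, labels, indicator, config, cv)
        assert len(result.folds) == 6
        # each fold holds exactly one test example
        assert all(f.tp + f.fp + f.fn <= 1 or (f.tp, f.fp, f.fn) == (0, 0, 0)
                   for f in result.folds)
        tested = sum(f.tp + f.fn for f in result.folds)  # positives seen in test
        assert tested == 3
        assert result == hd.cross_validate(x, labels, indicator, config, cv)

    def test_raising_c_plus_mostly_raises_training_recall(self):
        """Weak monotonicity of training-set recall in C+ (statistical: the
        solver tolerance allows occasional inversions)."""
        rng = np.random.default_rng(4)
        comparisons = violations = 0
        for _ in range(10):
            x = np.vstack([rng.normal(0.6, 1, (8, 2)), rng.normal(-0.6, 1, (24, 2))])
            y = np.array([1] * 8 + [-1] * 24)
            gram = x @ x.T
            recalls = []
            for c_plus in (0.25, 0.5, 1.0, 2.0, 4.0):
                model = hd.fit(gram, y, hd.TrainingConfig(c_plus=c_plus, c_minus=1.0))
                recalls.append(hd.precision_recall_f(hd.predict(model, gram), y).recall)
            for lo, hi in zip(recalls, recalls[1:]):
                comparisons += 1
                if hi < lo - 1e-9:
                    violations += 1
        assert violations <= 0.2 * comparisons


class TestGridSearch:
    def test_singleton_grids_reduce_to_cross_validate(self, default_features):
        features, labels, indicator = default_features
        cv = hd.CVConfig(10, 0)
        table = hd.grid_search(features, labels, indicator, [0.6], [1.0], [1.0], cv)
        assert len(table) == 1
        direct = hd.cross_validate(
            features, labels, indicator,
            hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=0.6)), cv,
        )
        assert table.loc[0, "fmeasure"] == pytest.approx(direct.fmeasure)

    def test_cartesian_row_count(self, default_features):
        features, labels, indicator = default_features
        table = hd.grid_search(features, labels, indicator,
                               [0.0, 0.4, 0.8], [0.5, 1.0], [0.5, 1.0],
                               hd.CVConfig(5, 0))
        assert len(table) == 12

    def test_empty_grid_rejected(self, default_features):
        features, labels, indicator = default_features
        with pytest.raises(ValueError):
            hd.grid_search(features, labels, indicator, [], [1.0], [1.0], hd.CVConfig(5, 0))

    def test_best_row_tie_breaking(self):
        table = pd.DataFrame([
            {"alpha": 0.4, "c_plus": 1, "c_minus": 1, "precision": 0.8, "recall": 0.9, "fmeasure": 0.9},
            {"alpha": 0.2, "c_plus": 1, "c_minus": 1, "precision": 0.9, "recall": 0.8, "fmeasure": 0.9},
            {"alpha": 0.6, "c_plus": 1, "c_minus": 1, "precision": 0.9, "recall": 0.8, "fmeasure": 0.9},
        ])
        best = select_best(table)
        assert best["alpha"] == 0.2  # higher precision first, then lower alpha


class TestFeatureContributions:
    def make_model(self, x, y, alpha=0.0):
        gram = x @ x.T
        return hd.fit(gram, y, hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=alpha)))

    def test_hand_arithmetic(self):
        # craft a model whose primal weights are exactly (1, -1, 0)
        x = np.array([[1.0, 0.0, 5.0], [0.0, 1.0, 5.0]])
        model = TrainedModel(
            support=np.array([0, 1]), dual_signed=np.array([1.0, -1.0]),
            bias=0.0, n_train=2,
            config=hd.TrainingConfig(1.0, 1.0, hd.KernelConfig(alpha=0.0)),
        )
        table = hd.feature_contributions(model, x, feature_names=["F1", "F2", "F3"])
        by_feature = table.set_index("feature")
        assert by_feature.loc["F1", "weight"] == pytest.approx(1.0)
        assert by_feature.loc["F2", "weight"] == pytest.approx(-1.0)
        assert by_feature.loc["F3", "weight"] == pytest.approx(0.0)
        assert by_feature.loc["F3", "product"] == pytest.approx(0.0)
        # products: F1 = 1*0.5, F2 = -1*0.5, F3 = 0 -> F1/F2 tie broken by order
        assert list(table["feature"][:2]) == ["F1", "F2"]

    def test_zero_column_has_zero_contribution(self):
        rng = np.random.default_rng(5)
        x = np.hstack([rng.normal(size=(20, 2)), np.zeros((20, 1))])
        x[:10, 0] += 3
        y = np.array([1] * 10 + [-1] * 10)
        model = self.make_model(x, y)
        table = hd.feature_contributions(model, x, feature_names=["a", "b", "zero"])
        assert table.set_index("feature").loc["zero", "product"] == 0.0

    def test_informative_feature_ranked_first(self):
        """When only the first feature separates the classes it dominates the
        weight-times-mean contribution ranking."""
        rng = np.random.default_rng(6)
        n = 30
        x = np.column_stack([
            np.concatenate([rng.uniform(0.8, 1.0, n), rng.uniform(0.0, 0.2, n)]),
            rng.uniform(0.4, 0.6, 2 * n),
            rng.uniform(0.4, 0.6, 2 * n),
        ])
        y = np.array([1] * n + [-1] * n)
        model = self.make_model(x, y)
        table = hd.feature_contributions(model, x, feature_names=["F1", "F2", "F3"])
        assert table.iloc[0]["feature"] == "F1"

    def test_requires_pure_linear_kernel(self, default_features):
        features, labels, _ = default_features
        x = features[20:60, :2]  # mixed slice: both classes present
        model = self.make_model(x, labels[20:60], alpha=0.5)
        with pytest.raises(ValueError):
            hd.feature_contributions(model, x)
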