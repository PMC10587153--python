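"""Serial fusion, classifier variants and the one-vs-rest metric suite."""

import numpy as np
import pandas as pd
import pytest

from vht_smear.classify import (VARIANTS, EvalReport, evaluate, fuse,
                                report_from_confusion, run_fusion_grid,
                                train_classifier)
from vht_smear.features import FeatureVector


def vec(n, source="vht", seed=0):
    return FeatureVector(values=np.random.default_rng(seed).normal(size=n),
                         source=source)


class TestFuse:
    @pytest.mark.parametrize("na,nb,expected", [
        (100, 100, 200), (200, 200, 400), (400, 320, 720), (750, 320, 1070),
    ])
    def test_serial_lengths(self, na, nb, expected):
        assert len(fuse(vec(na, "deep"), vec(nb))) == expected

    def test_order_preserved(self):
        a, b = vec(5, seed=1), vec(3, seed=2)
        fused = fuse(a, b)
        assert np.array_equal(fused.values[:5], a.values)
        assert np.array_equal(fused.values[5:], b.values)
        assert fused.source == "fused"

    def test_empty_is_identity_element(self):
        v = vec(7)
        empty = FeatureVector(values=np.array([]), source="vht")
        assert np.array_equal(fuse(empty, v).values, v.values)

    def test_associative(self):
        a, b, c = vec(2, seed=1), vec(3, seed=2), vec(4, seed=3)
        left = fuse(fuse(a, b), c)
        right = fuse(a, fuse(b, c))
        assert np.array_equal(left.values, right.values)


def blobs(n_per_class=30, n_classes=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = rng.normal(0, 1, size=2) * 0 + np.array(
            [sep * np.cos(2 * np.pi * c / n_classes),
             sep * np.sin(2 * np.pi * c / n_classes)])
        X.append(center + rng.normal(0, 1, size=(n_per_class, 2)))
        y += [f"c{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestTrainClassifier:
    def test_unknown_variant_lists_supported(self):
        X, y = blobs()
        with pytest.raises(ValueError, match="cubic-svm"):
            train_classifier(X, y, "super-svm")

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(10), "linear-svm")

    def test_cubic_perfect_on_separable_toy(self):
        X = np.array([[-2.0, 0], [-2, 1], [-3, -1], [2, 0], [2, 1], [3, -1]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = train_classifier(X, y, "cubic-svm")
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_fit_and_predict(self, variant):
        # large enough that even the coarse (k=100) KNN has a local majority
        X, y = blobs(n_per_class=80, seed=1)
        model = train_classifier(X, y, variant)
        assert (model.predict(X) == y).mean() > 0.5

    def test_fine_and_coarse_gaussian_differ(self):
        X, y = blobs(n_per_class=40, sep=2.5, seed=2)
        fine = train_classifier(X, y, "fine-gaussian-svm")
        coarse = train_classifier(X, y, "coarse-gaussian-svm")
        gx, gy = np.meshgrid(np.linspace(-5, 5, 25), np.linspace(-5, 5, 25))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        assert (fine.predict(grid) != coarse.predict(grid)).sum() >= 1


class TestMetricSuite:
    def test_headline_confusion_matrix_metrics(self):
        cm = np.array([[2496, 1, 0, 0],
                       [0, 2483, 0, 0],
                       [0, 0, 2478, 0],
                       [0, 0, 1, 2498]])
        labels = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")
        rep = report_from_confusion(cm, labels)
        assert np.isclose(rep.overall_accuracy, 9955 / 9957)
        sens = [rep.per_class[l]["sensitivity"] for l in labels]
        assert np.allclose(sens, [2496 / 2497, 1.0, 1.0, 2498 / 2499])
        assert np.isclose(rep.overall_accuracy + rep.error, 1.0)

    def test_perfect_predictions(self):
        cm = np.diag([5, 5, 5, 5])
        rep = report_from_confusion(cm, list("abcd"))
        assert rep.overall_accuracy == 1.0 and rep.error == 0.0
        for m in rep.per_class.values():
            assert all(v == 1.0 for v in m.values())

    def test_all_one_class_predictor_macro_sensitivity(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[:, 0] = 10  # everything predicted as the first class
        rep = report_from_confusion(cm, list("abcd"))
        assert np.isclose(rep.macro["sensitivity"], 0.25)

    def test_zero_over_zero_rates_are_zero(self):
        # class 'b' present in truth but never predicted: PPV = 0/0 -> 0
        cm = np.array([[5, 0], [3, 0]])
        rep = report_from_confusion(cm, ["a", "b"])
        assert rep.per_class["b"]["ppv"] == 0.0
        assert rep.per_class["b"]["f_measure"] == 0.0

    def test_absent_class_excluded_from_macro(self):
        cm = np.array([[4, 0, 0], [0, 6, 0], [0, 0, 0]])
        rep = report_from_confusion(cm, ["a", "b", "ghost"])
        assert rep.per_class["ghost"]["sensitivity"] is None
        assert rep.macro["sensitivity"] == 1.0

    def test_per_class_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, size=(4, 4))
        total = cm.sum()
        for i in range(4):
            tp = cm[i, i]
            fn = cm[i].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = total - tp - fn - fp
            assert tp + fn + fp + tn == total


class TestEvaluate:
    def test_report_on_fitted_model(self):
        X, y = blobs(seed=3)
        model = train_classifier(X, y, "linear-svm")
        rep = evaluate(model, X, y)
        assert isinstance(rep, EvalReport)
        assert rep.confusion.sum() == len(y)
        assert all(a is None or 0.97 <= a <= 1.0 for a in rep.auc.values())

    def test_empty_test_set_rejected(self):
        X, y = blobs()
        model = train_classifier(X, y, "linear-svm")
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 2)), np.array([]))

    def test_auc_of_perfect_ranker_is_one(self):
        class Stub:
            classes_ = np.array(["neg", "pos"])

            def predict(self, X):
                return np.where(X[:, 0] > 0, "pos", "neg")

            def decision_function(self, X):
                return X[:, 0]

        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = np.where(X[:, 0] > 0, "pos", "neg")
        rep = evaluate(Stub(), X, y)
        assert rep.auc["pos"] == 1.0

    def test_auc_of_random_scores_near_half(self):
        class RandomStub:
            classes_ = np.array(["n", "p"])

            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def predict(self, X):
                return np.where(self.rng.random(len(X)) > 0.5, "p", "n")

            def decision_function(self, X):
                return self.rng.normal(size=len(X))

        y = np.array(["n", "p"] * 100)
        X = np.zeros((200, 1))
        aucs = [evaluate(RandomStub(s), X, y).auc["p"] for s in range(10)]
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestFusionGrid:
    def make_tables(self, n=60, d_deep=40, d_vht=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(["a", "b", "c", "d"] * (n // 4))
        offsets = {"a": 0.0, "b": 2.0, "c": 4.0, "d": 6.0}
        shift = np.array([offsets[c] for c in y])[:, None]
        deep = pd.DataFrame(rng.normal(size=(n, d_deep)) + shift,
                            columns=[f"deep_{i:04d}" for i in range(d_deep)])
        vht = pd.DataFrame(rng.normal(size=(n, d_vht)) + shift,
                           columns=[f"vht_{i:03d}" for i in range(d_vht)])
        return deep, vht, y

    def test_fused_length_column(self):
        deep, vht, y = self.make_tables()
        df = run_fusion_grid(deep, vht, y, grid=[(10, 10), (20, 20)],
                             variants=["linear-svm"], seed=0,
                             aco_params=dict(ants=2, iterations=2))
        assert list(df["fused_length"]) == [20, 40]

    def test_empty_grid_gives_empty_report_with_header(self):
        deep, vht, y = self.make_tables()
        df = run_fusion_grid(deep, vht, y, grid=[], variants=["linear-svm"])
        assert df.empty and "accuracy" in df.columns

    def test_rerun_identical(self):
        deep, vht, y = self.make_tables(seed=1)
        kw = dict(grid=[(8, 8)], variants=["cubic-svm"], seed=3,
                  aco_params=dict(ants=2, iterations=2))
        pd.testing.assert_frame_equal(run_fusion_grid(deep, vht, y, **kw),
                                      run_fusion_grid(deep, vht, y, **kw))

    def test_excessive_grid_point_rejected(self):
        deep, vht, y = self.make_tables()
        with pytest.raises(ValueError):
            run_fusion_grid(deep, vht, y, grid=[(10, 999)])
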