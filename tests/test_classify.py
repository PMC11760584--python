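"""Tuning, fusion, metrics and the cross-validated harness."""

import math

import numpy as np
import pandas as pd
import pytest

from inkpd.classify import (
    AdaBoostParams,
    FamilyPrediction,
    FusionResult,
    PipelineConfig,
    compute_metrics,
    fuse_predictions,
    run_cv,
    train_family,
    tune_adaboost,
)
from inkpd.features import FeatureTable


def fam(probs, family="k"):
    p = np.asarray(probs, dtype=float)
    return FamilyPrediction(family=family, classes=np.arange(p.shape[1]), proba=p)


class TestParams:
    def test_ranges_enforced(self):
        AdaBoostParams(1, math.exp(-4), 1, math.exp(-6))
        AdaBoostParams(30, 1.0, 100, 10.0)
        for bad in [dict(max_depth=0), dict(max_depth=31),
                    dict(min_samples_split=0.001), dict(n_estimators=101),
                    dict(learning_rate=11.0)]:
            kwargs = dict(max_depth=3, min_samples_split=0.1,
                          n_estimators=10, learning_rate=1.0)
            kwargs.update(bad)
            with pytest.raises(ValueError):
                AdaBoostParams(**kwargs)


class TestTuning:
    @staticmethod
    def separable(n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = np.array(["HC", "PD"] * (n // 2))
        X[y == "PD", :2] += 3.0
        return X, y

    def test_tuned_params_in_range_and_accurate(self):
        X, y = self.separable()
        params, acc = tune_adaboost(X, y, n_coatis=10, n_iterations=3, seed=0)
        for field, (lo, hi) in AdaBoostParams.RANGES.items():
            assert lo <= getattr(params, field) <= hi
        assert acc >= 0.95

    def test_deterministic(self):
        X, y = self.separable(seed=2)
        a = tune_adaboost(X, y, n_coatis=6, n_iterations=2, seed=4)
        b = tune_adaboost(X, y, n_coatis=6, n_iterations=2, seed=4)
        assert a == b

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            tune_adaboost(X, np.array(["HC"] * 20), n_coatis=4, n_iterations=1)

    def test_train_family_capacity(self):
        X, y = self.separable(seed=1)
        model = train_family(X, y, AdaBoostParams(10, 0.05, 20, 1.0))
        assert model.score(X, y) == 1.0


class TestFusion:
    def test_hand_worked_four_family_case(self):
        fr = fuse_predictions([fam([[0.8, 0.2]]), fam([[0.6, 0.4]]),
                               fam([[0.7, 0.3]]), fam([[0.3, 0.7]])])
        np.testing.assert_allclose(fr.weights, [[0.75, 0.75, 0.75, 0.25]])
        np.testing.assert_allclose(fr.proba, [[1.65, 0.85]])
        assert fr.predicted[0] == 0

    def test_identical_vectors_preserve_argmax(self):
        p = [[0.2, 0.5, 0.3], [0.6, 0.1, 0.3]]
        fr = fuse_predictions([fam(p), fam(p), fam(p)])
        np.testing.assert_array_equal(fr.predicted, [1, 0])

    def test_single_family_is_identity(self):
        p = np.array([[0.3, 0.7], [0.9, 0.1]])
        fr = fuse_predictions([fam(p)])
        np.testing.assert_allclose(fr.weights, 1.0)
        np.testing.assert_allclose(fr.proba, p)

    def test_normalisation_preserves_argmax(self):
        rng = np.random.default_rng(0)
        preds = []
        for _ in range(4):
            p = rng.dirichlet(np.ones(3), size=20)
            preds.append(fam(p))
        raw = fuse_predictions(preds, normalize=False)
        norm = fuse_predictions(preds, normalize=True)
        np.testing.assert_array_equal(raw.predicted, norm.predicted)
        np.testing.assert_allclose(norm.weights.sum(axis=1), 1.0)

    def test_mismatched_classes_rejected(self):
        with pytest.raises(ValueError):
            fuse_predictions([fam([[0.5, 0.5]]), fam([[0.2, 0.3, 0.5]])])


class TestMetrics:
    @staticmethod
    def binary_result(y_pred):
        proba = np.stack([1.0 - y_pred, y_pred.astype(float)], axis=1)
        return FusionResult(np.array(["HC", "PD"]), np.ones((len(y_pred), 1)),
                            proba, y_pred)

    def test_hand_worked_confusion(self):
        # TP=9, FN=1, TN=8, FP=2 -> Acc 0.85, Sen 0.90, Spe 0.80
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        rep = compute_metrics(y_true, self.binary_result(y_pred))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)

    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        rep = compute_metrics(y, self.binary_result(y))
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.auc) == (
            1.0, 1.0, 1.0, 1.0)

    def test_three_class_perfect_macro(self):
        y = np.repeat([0, 1, 2], 5)
        proba = np.eye(3)[y]
        fr = FusionResult(np.array(["HC", "ET", "PD"]), np.ones((15, 1)),
                          proba, y)
        rep = compute_metrics(y, fr)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.auc == 1.0

    def test_agrees_with_bruteforce_confusion_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(10, 50))
            k = int(rng.integers(2, 4))
            y_true = rng.integers(0, k, n)
            if len(np.unique(y_true)) < k:
                continue
            proba = rng.dirichlet(np.ones(k), size=n)
            y_pred = proba.argmax(axis=1)
            fr = FusionResult(np.arange(k), np.ones((n, 1)), proba, y_pred)
            rep = compute_metrics(y_true, fr)
            # brute-force per-class one-vs-rest counts
            sens, spes = [], []
            for c in range(k):
                tp = sum(1 for a, b in zip(y_true, y_pred) if a == c and b == c)
                fn = sum(1 for a, b in zip(y_true, y_pred) if a == c and b != c)
                fp = sum(1 for a, b in zip(y_true, y_pred) if a != c and b == c)
                tn = n - tp - fn - fp
                sens.append(tp / (tp + fn))
                spes.append(tn / (tn + fp))
            assert rep.accuracy == pytest.approx(
                sum(a == b for a, b in zip(y_true, y_pred)) / n)
            if k > 2:
                assert rep.sensitivity == pytest.approx(np.mean(sens))
                assert rep.specificity == pytest.approx(np.mean(spes))
            else:
                assert rep.sensitivity == pytest.approx(sens[1])


def synthetic_feature_table(n_per_class=15, seed=0):
    """Two-family table with informative columns in each family."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["HC", "ET", "PD"], n_per_class)
    n = len(labels)
    y = np.repeat([0, 1, 2], n_per_class)
    cols, fams, data = [], {}, []
    for fam_name, n_feat in (("kinematic", 12), ("pressure", 8)):
        block = rng.normal(size=(n, n_feat))
        block[:, :3] += y[:, None] * 2.5
        data.append(block)
        names = [f"{fam_name[:1].upper()}__f{j}" for j in range(n_feat)]
        cols += names
        fams.update({c: fam_name for c in names})
    df = pd.DataFrame(np.hstack(data), columns=cols,
                      index=[f"r{i}" for i in range(n)])
    return FeatureTable(df, fams, pd.Series(labels, index=df.index))


QUICK = PipelineConfig(n_outer_folds=5, n_inner_folds=3, top_k=5, rf_trees=50,
                       n_coatis=6, n_iterations=2, seed=0)


class TestRunCv:
    def test_folds_disjoint_stratified_and_leakage_safe(self):
        table = synthetic_feature_table()
        report, art = run_cv(table, config=QUICK)
        all_test = [rid for fold in art.fold_rows.values() for rid in fold]
        assert sorted(all_test) == sorted(table.data.index)  # disjoint cover
        assert len(art.fold_rows) == 5
        # every selection was fitted on exactly the complement of its fold
        for (fold, family), feats in art.selected.items():
            assert len(feats) <= QUICK.top_k
        assert report.accuracy >= 0.8  # strongly informative features

    def test_deterministic_report(self):
        table = synthetic_feature_table(seed=3)
        a, _ = run_cv(table, config=QUICK)
        b, _ = run_cv(table, config=QUICK)
        assert a.as_dict() == b.as_dict()

    def test_too_few_samples_per_class_rejected(self):
        table = synthetic_feature_table(n_per_class=4)
        with pytest.raises(ValueError, match="per class"):
            run_cv(table, config=QUICK)
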