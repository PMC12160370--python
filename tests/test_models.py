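"""Classifier benchmark, the confusion-count metric suite, and CV plumbing."""

import numpy as np
import pandas as pd
import pytest

from tonguedx.models import (
    ALGORITHMS,
    ConfusionCounts,
    FusionMLPSpec,
    aggregate_fold_aucs,
    auc_ovr,
    binary_metrics,
    cross_validate,
    fuse_features,
    metrics,
    rank_importance,
    split_train_test,
    train_model,
)
from tonguedx.selection import make_screening_benchmark


class TestSplit:
    def test_80_20_arithmetic(self, rng):
        y = rng.integers(0, 2, 100)
        train, test = split_train_test(np.zeros((100, 2)), y, ratio=0.2, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert len(set(train) & set(test)) == 0
        assert len(set(train) | set(test)) == 100

    def test_stratification_preserves_class_shares(self):
        y = np.array([0] * 50 + [1] * 10)
        _, test = split_train_test(np.zeros((60, 1)), y, ratio=0.2, seed=1)
        assert (y[test] == 0).sum() == 10 and (y[test] == 1).sum() == 2

    def test_same_seed_identical_split(self, rng):
        y = rng.integers(0, 3, 90)
        a = split_train_test(np.zeros((90, 1)), y, seed=7)
        b = split_train_test(np.zeros((90, 1)), y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.zeros((10, 1)), np.zeros(10), ratio=1.5)


class TestTrainModel:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_toy_fits_perfectly(self, algorithm, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        model = train_model(algorithm, X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0
        proba = model.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_fusion_mlp_parameter_count(self, rng):
        """37 inputs -> two hidden layers of 8 -> 5 outputs = 421 weights."""
        spec = FusionMLPSpec(37, (8, 8), 5)
        assert spec.parameter_count() == 37 * 8 + 8 + 8 * 8 + 8 + 8 * 5 + 5 == 421
        X = rng.normal(size=(100, 37))
        y = rng.integers(0, 5, 100)
        model = train_model("mlp", X, y, {"spec": FusionMLPSpec(37, (8, 8), 5, epochs=15)})
        fitted = sum(w.size for w in model.coefs_) + sum(b.size for b in model.intercepts_)
        assert fitted == 421

    def test_knn_with_k1_memorizes(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30)
        model = train_model("knn", X, y, {"n_neighbors": 1})
        assert (model.predict(X) == y).mean() == 1.0

    def test_unknown_algorithm_and_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_model("svm", np.zeros((4, 2)), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="non-finite"):
            train_model("knn", np.array([[np.nan, 1.0]] * 4), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="2 classes"):
            train_model("knn", np.zeros((4, 2)), np.array([1, 1, 1, 1]))


class TestMetricFormulas:
    def test_perfect_prediction(self):
        r = binary_metrics(ConfusionCounts(tp=10, tn=30, fp=0, fn=0), auc=1.0)
        for f in ("accuracy", "precision", "sensitivity", "specificity", "f1",
                  "auc", "mcc", "kap", "npv"):
            assert getattr(r, f) == pytest.approx(1.0)

    def test_hand_evaluated_counts(self):
        # TP=50 TN=40 FP=10 FN=0
        r = binary_metrics(ConfusionCounts(50, 40, 10, 0))
        assert r.accuracy == pytest.approx(0.9)
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(0.8)
        assert r.precision == pytest.approx(5 / 6)
        assert r.f1 == pytest.approx(10 / 11)
        assert r.mcc == pytest.approx((50 * 40 - 0) / np.sqrt(60 * 50 * 50 * 40))
        assert r.npv == pytest.approx(1.0)
        assert r.ppv == r.precision and r.recall == r.sensitivity

    def test_constant_predictor_has_zero_kappa(self):
        # predict everything positive on a mixed sample
        y_true = np.array([1] * 30 + [0] * 70)
        y_pred = np.ones(100, dtype=int)
        per, _ = metrics(y_true, y_pred, classes=np.array([0, 1]))
        assert per[1].kap == pytest.approx(0.0)

    def test_matches_brute_force_tally_on_random_predictions(self, rng):
        """Oracle: independent per-pair counting over 200 multiclass draws."""
        classes = np.array([0, 1, 2, 3, 4])
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        scores = rng.random((200, 5))
        scores /= scores.sum(axis=1, keepdims=True)
        per, macro = metrics(y_true, y_pred, scores, classes)
        for k in classes:
            tp = sum(1 for t, p in zip(y_true, y_pred) if p == k and t == k)
            fp = sum(1 for t, p in zip(y_true, y_pred) if p == k and t != k)
            fn = sum(1 for t, p in zip(y_true, y_pred) if p != k and t == k)
            tn = 200 - tp - fp - fn
            r = per[k]
            assert r.accuracy == pytest.approx((tp + tn) / 200, abs=1e-10)
            assert r.precision == pytest.approx(tp / (tp + fp), abs=1e-10)
            assert r.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-10)
            assert r.specificity == pytest.approx(tn / (tn + fp), abs=1e-10)
            num = tp * tn - fp * fn
            den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            assert r.mcc == pytest.approx(num / den, abs=1e-10)

    def test_auc_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 3, 120)
        scores = rng.random((120, 3))
        scores /= scores.sum(axis=1, keepdims=True)
        _, macro = metrics(y, scores.argmax(1), scores, np.array([0, 1, 2]))
        ref = roc_auc_score(y, scores, multi_class="ovr", average="macro")
        assert macro.auc == pytest.approx(ref, abs=1e-10)

    def test_kappa_never_exceeds_accuracy(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            per, _ = metrics(y_true, y_pred, classes=np.array([0, 1, 2]))
            for r in per.values():
                if np.isfinite(r.kap):
                    assert r.kap <= r.accuracy + 1e-12

    def test_mcc_near_zero_under_label_permutation(self, rng):
        """Predictions independent of truth carry no correlation."""
        y_true = rng.integers(0, 2, 2000)
        y_pred = rng.permutation(y_true)
        per, _ = metrics(y_true, y_pred, classes=np.array([0, 1]))
        assert abs(per[1].mcc) < 0.1

    def test_zero_denominator_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            r = binary_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert np.isnan(r.precision)


class TestCrossValidation:
    def test_printed_fold_aucs_aggregate(self):
        mean, se = aggregate_fold_aucs([0.906, 0.846, 0.890, 0.938, 0.852])
        assert round(mean, 3) == 0.886
        assert round(se, 4) == 0.0171

    def test_identical_folds_zero_se(self):
        mean, se = aggregate_fold_aucs([0.9, 0.9, 0.9])
        assert mean == 0.9 and se == 0.0

    def test_leave_one_out_produces_n_folds(self):
        X, y, _ = make_screening_benchmark(0, n=10, p=4, k=2, n_classes=2)
        report = cross_validate("knn", X, y, k=10, seed=0, params={"n_neighbors": 1})
        assert len(report.fold_metrics) == 10

    def test_folds_partition_samples(self):
        X, y, _ = make_screening_benchmark(1, n=60, p=5, n_classes=3)
        report = cross_validate("decision_tree", X, y, k=5, seed=0)
        all_idx = np.concatenate(report.fold_assignments)
        assert sorted(all_idx) == list(range(60))

    def test_mean_auc_is_mean_of_fold_aucs(self):
        X, y, _ = make_screening_benchmark(2, n=100, p=8, n_classes=3)
        report = cross_validate("random_forest", X, y, k=4, seed=0,
                                params={"n_estimators": 30})
        assert report.mean_auc == pytest.approx(
            np.mean([m.auc for m in report.fold_metrics])
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            cross_validate("knn", np.zeros((4, 2)), np.array([0, 1, 0, 1]), k=1)


class TestFusion:
    def make_tables(self, rng):
        ids = [f"s{i}" for i in range(10)]
        trad = pd.DataFrame(rng.normal(size=(10, 3)), index=ids,
                            columns=["lab_mean_a", "glcm_asm", "glcm_contrast"])
        deep = pd.DataFrame(rng.normal(size=(10, 4)), index=ids,
                            columns=["DL_0", "DL_1", "DL_2", "DL_3"])
        demo = pd.DataFrame({"age": rng.integers(20, 60, 10), "sex": rng.integers(0, 2, 10)},
                            index=ids)
        return trad, deep, demo

    def test_column_order_traditional_demographics_deep(self, rng):
        trad, deep, demo = self.make_tables(rng)
        fused = fuse_features(trad, deep, ["lab_mean_a", "glcm_asm"], ["DL_1", "DL_3"], demo)
        assert list(fused.columns) == ["lab_mean_a", "glcm_asm", "age", "sex", "DL_1", "DL_3"]

    def test_11_plus_26_gives_37_inputs(self, rng):
        ids = [f"s{i}" for i in range(8)]
        trad = pd.DataFrame(rng.normal(size=(8, 11)), index=ids,
                            columns=[f"t{i}" for i in range(11)])
        deep = pd.DataFrame(rng.normal(size=(8, 30)), index=ids,
                            columns=[f"DL_{i}" for i in range(30)])
        fused = fuse_features(trad, deep, list(trad.columns), [f"DL_{i}" for i in range(26)])
        assert fused.shape[1] == 37

    def test_empty_deep_selection_degrades_to_traditional(self, rng):
        trad, deep, _ = self.make_tables(rng)
        fused = fuse_features(trad, deep, ["glcm_asm"], [])
        assert list(fused.columns) == ["glcm_asm"]

    def test_duplicate_feature_name_rejected(self, rng):
        trad, deep, _ = self.make_tables(rng)
        deep = deep.rename(columns={"DL_0": "glcm_asm"})
        with pytest.raises(ValueError, match="duplicated"):
            fuse_features(trad, deep, ["glcm_asm"], ["glcm_asm"])

    def test_id_mismatch_rejected(self, rng):
        trad, deep, _ = self.make_tables(rng)
        with pytest.raises(ValueError, match="sample ids"):
            fuse_features(trad, deep.iloc[:5], ["glcm_asm"], ["DL_0"])


class TestRankImportance:
    def test_planted_dominant_feature_ranks_first(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.integers(0, 2, 120)
            X = pd.DataFrame(r.normal(size=(120, 6)),
                             columns=[f"c{i}" for i in range(6)])
            X["c0"] += 4.0 * y
            ranking = rank_importance(X, y, n_trees=100, seed=seed)
            assert ranking[0][0] == "c0"

    def test_all_noise_importances_stay_diffuse(self, rng):
        y = rng.integers(0, 2, 150)
        X = pd.DataFrame(rng.normal(size=(150, 10)), columns=[f"c{i}" for i in range(10)])
        ranking = rank_importance(X, y, n_trees=200, seed=0)
        vals = np.array([v for _, v in ranking])
        assert vals.max() < 3.0 * vals.mean()

    def test_output_covers_all_columns(self, rng):
        y = rng.integers(0, 2, 50)
        X = pd.DataFrame(rng.normal(size=(50, 7)), columns=[f"c{i}" for i in range(7)])
        ranking = rank_importance(X, y, n_trees=50, seed=0)
        assert len(ranking) == 7
        assert {n for n, _ in ranking} == set(X.columns)
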