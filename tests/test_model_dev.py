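import numpy as np
import pandas as pd
import pytest

from oxiscreen.errors import ConfigurationError, ContractError
from oxiscreen.model_dev import (
    ALL_FAMILIES,
    EvalMetrics,
    ModelFamily,
    ModelSpec,
    SubsetResult,
    TrainedModel,
    ZScaler,
    build_estimator,
    cross_validate,
    enumerate_subsets,
    evaluate,
    finalize_and_validate,
    fit_fold,
    mean_metrics,
    rank_auc,
    rank_results,
    resolved_hyperparameters,
    results_table,
    smote_oversample,
    subset_search,
    zscore_fit_apply,
)
from oxiscreen.oximetry_summary import FEATURE_NAMES

from conftest import concordance_auc_oracle, make_feature_table


class TestZscore:
    def test_two_point_example(self):
        train = np.array([[0.0], [10.0]])
        scaled, scaler = zscore_fit_apply(train)
        assert scaler.mu[0] == 5.0 and scaler.sigma[0] == 5.0
        np.testing.assert_allclose(scaled.ravel(), [-1.0, 1.0])

    def test_external_transform(self):
        train = np.array([[0.0], [10.0]])
        _, ext, _ = zscore_fit_apply(train, np.array([[5.0]]))
        assert ext[0, 0] == 0.0

    def test_constant_feature_maps_to_zero(self):
        train = np.full((5, 2), 7.0)
        train[:, 1] = [1, 2, 3, 4, 5]
        scaled, scaler = zscore_fit_apply(train)
        np.testing.assert_array_equal(scaled[:, 0], 0.0)
        assert np.isfinite(scaled).all()


class TestSmote:
    def test_balanced_unchanged(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        y = np.array([0, 1] * 5)
        X2, y2 = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_balances_and_synthetic_on_segments(self):
        rng = np.random.default_rng(0)
        X_min = rng.normal(0, 1, (10, 3))
        X_maj = rng.normal(5, 1, (50, 3))
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * 10 + [0] * 50)
        X2, y2 = smote_oversample(X, y, k=5, seed=1)
        assert np.sum(y2 == 1) == np.sum(y2 == 0) == 50
        np.testing.assert_array_equal(X2[:60], X)  # originals verbatim
        synth = X2[60:]
        # geometric membership: each synthetic point lies on a segment between
        # two minority points
        for s in synth:
            on_segment = False
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    d = X_min[j] - X_min[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    lam = (s - X_min[i]) @ d / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                            X_min[i] + lam * d, s, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_lambda_zero_limit_duplicates(self):
        # minority of size one degenerates to exact duplication (λ·0 ≡ 0)
        X = np.vstack([[0.0, 0.0], np.ones((4, 2))])
        y = np.array([1, 0, 0, 0, 0])
        X2, y2 = smote_oversample(X, y, seed=2)
        synth = X2[5:]
        np.testing.assert_array_equal(synth, np.zeros((3, 2)))

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            smote_oversample(np.zeros((5, 2)), np.ones(5), seed=0)

    def test_k_reduced_when_minority_small(self):
        X = np.vstack([np.random.default_rng(3).normal(0, 1, (3, 2)),
                       np.random.default_rng(4).normal(5, 1, (20, 2))])
        y = np.array([1] * 3 + [0] * 20)
        X2, y2 = smote_oversample(X, y, k=5, seed=3)
        assert np.sum(y2 == 1) == 20


class TestEvaluate:
    def test_closed_form_confusion(self):
        scores = np.concatenate([np.full(90, 0.9), np.full(10, 0.1),
                                 np.full(90, 0.1), np.full(10, 0.9)])
        labels = np.concatenate([np.ones(100), np.zeros(100)]).astype(int)
        m = evaluate(scores, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (90, 10, 90, 10)
        for v in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv, m.f1):
            assert v == pytest.approx(0.9)

    def test_perfect_ordering_auc_one(self):
        scores = np.linspace(0, 1, 20)
        labels = (scores > 0.5).astype(int)
        assert evaluate(scores, labels).auc == 1.0

    def test_auc_matches_concordance_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            scores = rng.integers(0, 10, 50) / 10.0  # discrete → ties exercised
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert rank_auc(scores, labels) == pytest.approx(
                concordance_auc_oracle(scores, labels), abs=1e-12)

    def test_f1_identity_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(1, 200, 4)
            scores = np.concatenate([np.full(tp + fp, 0.9), np.full(tn + fn, 0.1)])
            labels = np.concatenate([np.ones(tp), np.zeros(fp),
                                     np.zeros(tn), np.ones(fn)]).astype(int)
            m = evaluate(scores, labels)
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert m.f1 == pytest.approx(
                2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        a = rank_auc(scores, labels)
        assert rank_auc(np.exp(5 * scores), labels) == pytest.approx(a, abs=1e-12)
        assert rank_auc(scores ** 3, labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_auc_nan(self):
        m = evaluate(np.array([0.2, 0.8]), np.array([1, 1]))
        assert np.isnan(m.auc)
        assert m.sensitivity == 0.5


class TestModelSpec:
    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(ModelFamily.LOGISTIC, {"max_depth": 3})

    def test_all_families_buildable(self):
        X = np.random.default_rng(1).normal(0, 1, (60, 3))
        y = (X[:, 0] > 0).astype(int)
        for family in ALL_FAMILIES:
            est = build_estimator(ModelSpec(family, seed=0))
            est.fit(X, y)
            proba = est.predict_proba(X)
            assert proba.shape == (60, 2)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_resolved_hyperparameters_record(self):
        rec = resolved_hyperparameters(ModelSpec(ModelFamily.GBT_ORDERED))
        assert rec["mapped"]["learning_rate"] == 0.03
        assert rec["mapped"]["l2_leaf_reg"] == 3
        assert rec["unmapped"] == {"loss_function": "Logloss"}


class TestCrossValidate:
    def test_stratification_and_partition(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        res = cross_validate(X, y, ModelSpec(ModelFamily.LOGISTIC), seed=0)
        assert len(res.fold_metrics) == 5
        # validation folds partition the cohort
        n_eval = sum(m.tp + m.fp + m.tn + m.fn for m in res.fold_metrics)
        assert n_eval == len(y)
        # fold class proportions within one subject of the cohort proportion
        pos_rate = y.mean()
        for m in res.fold_metrics:
            n_fold = m.tp + m.fp + m.tn + m.fn
            n_pos = m.tp + m.fn
            assert abs(n_pos - pos_rate * n_fold) <= 1.0

    def test_no_leakage_validation_labels_ignored(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)].to_numpy()
        y = feature_table["label"].to_numpy().astype(int)
        train_idx = np.arange(0, 90)
        val_idx = np.arange(90, len(y))
        spec = ModelSpec(ModelFamily.RANDOM_FOREST)
        scaler1, est1 = fit_fold(X, y, train_idx, spec, fold_seed=0)
        y_corrupt = y.copy()
        y_corrupt[val_idx] = 1 - y_corrupt[val_idx]
        scaler2, est2 = fit_fold(X, y_corrupt, train_idx, spec, fold_seed=0)
        np.testing.assert_array_equal(scaler1.mu, scaler2.mu)
        np.testing.assert_array_equal(scaler1.sigma, scaler2.sigma)
        probe = scaler1.transform(X[val_idx])
        np.testing.assert_array_equal(est1.predict_proba(probe),
                                      est2.predict_proba(probe))

    def test_separable_cohort_high_auc_all_families(self):
        table = make_feature_table(n=200, effect=8.0, seed=21)
        X = table[list(FEATURE_NAMES)]
        y = table["label"].to_numpy()
        for family in ALL_FAMILIES:
            res = cross_validate(X, y, ModelSpec(family), seed=1)
            assert res.metrics.auc >= 0.99, family

    def test_too_few_per_class(self):
        X = pd.DataFrame({"a": np.arange(8.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ContractError):
            cross_validate(X, y, ModelSpec(ModelFamily.LOGISTIC))

    def test_deterministic(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        a = cross_validate(X, y, ModelSpec(ModelFamily.GBT_LEAFWISE), seed=7)
        b = cross_validate(X, y, ModelSpec(ModelFamily.GBT_LEAFWISE), seed=7)
        assert a.metrics == b.metrics


class TestSubsetSearch:
    def test_subset_counts(self):
        assert len(enumerate_subsets({2})) == 28
        assert len(enumerate_subsets({3})) == 56
        assert len(enumerate_subsets({4})) == 70
        assert len(enumerate_subsets({1, 2, 3, 4})) == 162

    def test_counts_match_binomial_oracle(self):
        import math
        for k in range(1, 9):
            assert len(enumerate_subsets({k})) == math.comb(8, k)

    def test_cell_count_and_ranking(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        results = subset_search(X, y, sizes={1}, families=[ModelFamily.LOGISTIC],
                                n_folds=5, seed=0)
        assert len(results) == 8
        f1s = [r.metrics.f1 for r in results]
        assert f1s == sorted(f1s, reverse=True)

    def test_tie_break_f1_then_auc_then_name(self):
        def cell(features, f1, auc):
            m = EvalMetrics(1, 1, 1, 1, 0.5, 0.5, 0.5, f1, auc, 0.5, 0.5)
            return SubsetResult(features, ModelSpec(ModelFamily.LOGISTIC), [m], m)

        a = cell(("ODI",), 0.9, 0.8)
        b = cell(("HB",), 0.9, 0.95)
        c = cell(("AttnEn",), 0.9, 0.95)
        ranked = rank_results([a, b, c])
        assert [r.features for r in ranked] == [("AttnEn",), ("HB",), ("ODI",)]

    def test_unknown_feature_rejected(self, feature_table):
        with pytest.raises(ConfigurationError):
            subset_search(feature_table[["ODI", "HB"]],
                          feature_table["label"].to_numpy(), sizes={1})

    def test_results_table_layout(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        results = subset_search(X, y, sizes={1}, families=[ModelFamily.LOGISTIC])
        table = results_table(results)
        assert len(table) == 8
        assert {"rank", "features", "family", "mean_f1", "mean_auc"} <= set(table.columns)


class TestFinalize:
    def test_no_oversampling_in_retraining(self, feature_table, monkeypatch):
        import oxiscreen.model_dev as md

        def boom(*a, **k):
            raise AssertionError("oversampler must not run during finalization")

        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        best = subset_search(X, y, sizes={1}, families=[ModelFamily.LOGISTIC])[0]
        monkeypatch.setattr(md, "smote_oversample", boom)
        model, internal, external = finalize_and_validate(best, X, y, X, y)
        assert isinstance(model, TrainedModel)

    def test_external_prediction_count_and_alignment(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        best = subset_search(X, y, sizes={2}, families=[ModelFamily.LOGISTIC])[0]
        model, _, _ = finalize_and_validate(best, X, y, X, y)
        scores = model.predict_proba(X)
        assert len(scores) == len(X)
        # column order must not matter (name-based alignment)
        shuffled = X[list(reversed(X.columns))]
        np.testing.assert_array_equal(model.predict_proba(shuffled), scores)

    def test_feature_mismatch_rejected(self, feature_table):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        best = subset_search(X, y, sizes={1}, families=[ModelFamily.LOGISTIC])[0]
        bad_external = X.drop(columns=[best.features[0]])
        with pytest.raises(ContractError):
            finalize_and_validate(best, X, y, bad_external, y)

    def test_strong_effect_external_f1(self):
        internal = make_feature_table(n=300, effect=6.0, seed=31)
        external = make_feature_table(n=100, effect=6.0, seed=32)
        Xi, yi = internal[list(FEATURE_NAMES)], internal["label"].to_numpy()
        Xe, ye = external[list(FEATURE_NAMES)], external["label"].to_numpy()
        best = subset_search(Xi, yi, sizes={2},
                             families=[ModelFamily.LOGISTIC, ModelFamily.RANDOM_FOREST],
                             seed=2)[0]
        _, _, ext = finalize_and_validate(best, Xi, yi, Xe, ye)
        assert ext.f1 >= 0.9

    def test_model_roundtrip(self, feature_table, tmp_path):
        X = feature_table[list(FEATURE_NAMES)]
        y = feature_table["label"].to_numpy()
        best = subset_search(X, y, sizes={1}, families=[ModelFamily.GBT_ORDERED])[0]
        model, internal, _ = finalize_and_validate(best, X, y, X, y)
        p = tmp_path / "model.pkl"
        model.save(p)
        back = TrainedModel.load(p)
        np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))


def test_mean_metrics_aggregation():
    a = EvalMetrics(10, 0, 10, 0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    b = EvalMetrics(5, 5, 5, 5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    m = mean_metrics([a, b])
    assert m.tp == 15 and m.fn == 5
    assert m.f1 == pytest.approx(0.75)
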