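"""Classifier training, metric formulas, curves, CV, ablation, DMS bench."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from savpred.classifier_eval import (
    ConfusionCounts,
    TrainParams,
    TrainedModel,
    ablation,
    benchmark_dms,
    classify,
    kfold_cv,
    metrics,
    predict_proba,
    roc_pr,
    stratify_by_orthologs,
    train,
)
from savpred.feature_table import FeatureMatrix, impute
from savpred.fixtures import FixtureSpec, synth_feature_dataset

FAST = TrainParams(n_estimators=60, max_depth=3, seed=0)


def pair_ordering_auroc(labels, scores):
    """Exhaustive tie-aware pair statistic: P(score_pos > score_neg) + ties/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestMetrics:
    def test_worked_confusion_case(self):
        rep = metrics(ConfusionCounts(tp=9, tn=8, fp=1, fn=2))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(9 / 11)
        assert rep.specificity == pytest.approx(8 / 9)
        assert rep.f1 == pytest.approx(9 / (9 + 0.5 * 3))
        assert rep.mcc == pytest.approx(70 / math.sqrt(9900))
        assert rep.balanced_accuracy == pytest.approx((9 / 11 + 8 / 9) / 2)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        for name in ("accuracy", "sensitivity", "specificity", "f1", "mcc"):
            assert getattr(rep, name) == 1.0

    def test_balanced_errors_zero_mcc(self):
        rep = metrics(ConfusionCounts(tp=4, tn=9, fp=6, fn=6))
        assert rep.mcc == pytest.approx(0.0)

    def test_zero_denominator_reported_as_zero_with_flag(self):
        rep = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert rep.sensitivity == 0.0
        assert any("sensitivity" in f for f in rep.flags)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 40), tn=st.integers(0, 40),
        fp=st.integers(0, 40), fn=st.integers(0, 40),
    )
    def test_matches_sklearn_recomputation(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        from sklearn.metrics import (
            accuracy_score, f1_score, matthews_corrcoef, recall_score,
        )

        y = np.array([1] * (tp + fn) + [0] * (tn + fp))
        p = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        rep = metrics(ConfusionCounts.from_predictions(y, p))
        assert rep.accuracy == pytest.approx(accuracy_score(y, p))
        if tp + fn:
            assert rep.sensitivity == pytest.approx(
                recall_score(y, p, pos_label=1, zero_division=0))
        if tn + fp:
            assert rep.specificity == pytest.approx(
                recall_score(y, p, pos_label=0, zero_division=0))
        if tp + fp + fn:
            assert rep.f1 == pytest.approx(
                f1_score(y, p, zero_division=0))
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        if denom:
            assert rep.mcc == pytest.approx(matthews_corrcoef(y, p))


class TestRocPr:
    def test_perfect_ranking(self):
        curves = roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert curves.auroc == 1.0
        assert curves.aupr == pytest.approx(1.0)

    def test_reversed_ranking(self):
        assert roc_pr([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]).auroc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([1, 1, 1], [0.1, 0.2, 0.3])

    def test_trapezoid_equals_pair_ordering_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # many ties
            assert roc_pr(y, s).auroc == pytest.approx(
                pair_ordering_auroc(y, s), abs=1e-12
            )


class TestClassify:
    def test_strict_threshold(self):
        assert classify([0.51, 0.5, 0.49]).tolist() == [1, 0, 0]

    def test_length_preserved(self, rng):
        probs = rng.random(17)
        assert len(classify(probs)) == 17


def _small_dataset(seed=0, n=120, missingness=0.0):
    spec = FixtureSpec(seed=seed, n_pathogenic=n, n_neutral=n,
                       missingness=missingness)
    return synth_feature_dataset(spec)


class TestTrain:
    def test_separable_data_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(60, 2)),
                       rng.normal(3, 0.3, size=(60, 2))])
        y = np.array([0] * 60 + [1] * 60)
        model = train(X, y, FAST)
        preds = classify(predict_proba(model, X))
        assert np.array_equal(preds, y)

    def test_deterministic_for_fixed_seed(self):
        matrix, labels, _ = _small_dataset()
        filled = impute(matrix, np.ones(len(matrix), dtype=bool))
        p1 = predict_proba(train(filled.df, labels, FAST), filled.df)
        p2 = predict_proba(train(filled.df, labels, FAST), filled.df)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones(10), FAST)

    def test_missing_cells_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            train(X, np.array([0, 1] * 5), FAST)

    def test_wrong_feature_count_rejected(self):
        matrix, labels, _ = _small_dataset()
        filled = impute(matrix, np.ones(len(matrix), dtype=bool))
        model = train(filled.df, labels, FAST)
        with pytest.raises(ValueError, match="15"):
            predict_proba(model, np.ones((3, 4)))

    def test_save_load_round_trip(self):
        matrix, labels, _ = _small_dataset()
        filled = impute(matrix, np.ones(len(matrix), dtype=bool))
        model = train(filled.df, labels, FAST)
        again = TrainedModel.load(model.save())
        assert again.feature_names == model.feature_names
        assert np.allclose(
            predict_proba(again, filled.df),
            predict_proba(model, filled.df),
        )


class TestKfoldCv:
    def test_partition_and_stratification(self):
        matrix, labels, _ = _small_dataset(seed=5, n=50)
        res = kfold_cv(matrix, k=10, seed=1, params=FAST)
        assert np.all(res.fold_assignments >= 0)
        y = res.labels
        global_rate = y.mean()
        for fold in range(10):
            mask = res.fold_assignments == fold
            assert mask.sum() == len(matrix) // 10
            # within one sample of the global class proportion
            assert abs(y[mask].sum() - global_rate * mask.sum()) <= 1

    def test_deterministic_for_fixed_seed(self):
        matrix, labels, _ = _small_dataset(seed=5, n=60, missingness=0.1)
        r1 = kfold_cv(matrix, k=5, seed=3, params=FAST)
        r2 = kfold_cv(matrix, k=5, seed=3, params=FAST)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        for key in r1.mean:
            assert abs(r1.mean[key] - r2.mean[key]) < 1e-12

    def test_strong_separation_high_accuracy(self):
        spec = FixtureSpec(seed=9, n_pathogenic=100, n_neutral=100,
                           feature_shifts={"delta_psic": 4.0, "fis": 4.0})
        matrix, _, _ = synth_feature_dataset(spec)
        res = kfold_cv(matrix, k=5, seed=0, params=FAST)
        assert res.mean["accuracy"] > 0.95

    def test_k_larger_than_class_rejected(self):
        matrix, labels, _ = _small_dataset(n=4)
        with pytest.raises(ValueError, match="k="):
            kfold_cv(matrix, k=10, seed=0, params=FAST)

    def test_pooled_curves_cover_all_rows(self):
        matrix, labels, _ = _small_dataset(n=40)
        res = kfold_cv(matrix, k=4, seed=0, params=FAST)
        assert not np.isnan(res.oof_scores).any()
        curves = res.pooled_curves()
        assert 0.5 < curves.auroc <= 1.0


class TestAblation:
    def test_planted_feature_matters_more_than_noise(self):
        spec = FixtureSpec(
            seed=21, n_pathogenic=250, n_neutral=250,
            vn_pathogenic_mean=0.3, vn_pathogenic_var=0.04,
            vn_neutral_mean=0.3, vn_neutral_var=0.04,  # vn uninformative
            feature_shifts={"delta_psic": 2.5},
        )
        matrix, _, _ = synth_feature_dataset(spec)
        table = ablation(matrix, k=4, seed=2, params=FAST)
        assert len(table) == 15
        assert set(table["excluded_feature"]) == set(matrix.feature_names)
        drops = table.set_index("excluded_feature")["accuracy_drop"]
        noise = [f for f in matrix.feature_names
                 if f not in ("delta_psic",)]
        assert drops["delta_psic"] > max(abs(drops[f]) for f in noise)

    def test_empty_exclusion_reproduces_full_model(self):
        matrix, _, _ = _small_dataset(seed=2, n=40)
        full = kfold_cv(matrix, k=4, seed=0, params=FAST)
        again = kfold_cv(matrix.drop_features([]), k=4, seed=0, params=FAST)
        assert full.mean == again.mean


class TestStratifyByOrthologs:
    def test_threshold_zero_matches_unstratified(self):
        matrix, labels, counts = _small_dataset(seed=4, n=100)
        res = stratify_by_orthologs(
            matrix, None, counts.to_dict(), thresholds=[0], k=5,
            params=FAST,
        )
        full = kfold_cv(matrix, k=5, seed=0, params=FAST)
        assert res[0] == pytest.approx(full.mean["accuracy"])

    def test_accuracies_stable_when_signal_is_count_independent(self):
        matrix, labels, counts = _small_dataset(seed=4, n=400)
        res = stratify_by_orthologs(
            matrix, None, counts.to_dict(),
            thresholds=[0, 50, 100, 150, 200], k=5, params=FAST,
        )
        values = [v for v in res.values() if v is not None]
        assert len(values) == 5
        assert max(values) - min(values) < 0.05

    def test_empty_stratum_skipped_with_warning(self):
        matrix, labels, counts = _small_dataset(seed=4, n=30)
        with pytest.warns(UserWarning, match="stratum"):
            res = stratify_by_orthologs(
                matrix, None, counts.to_dict(), thresholds=[10_000], k=3,
                params=FAST,
            )
        assert res[10_000] is None


class TestBenchmarkDms:
    def _series(self, values):
        idx = pd.Index([f"v{i}" for i in range(len(values))])
        return pd.Series(values, index=idx)

    def test_monotone_predictions_perfect_rank_correlation(self):
        preds = self._series([0.1, 0.3, 0.5, 0.9])
        dms = self._series([1.0, 0.8, 0.4, 0.2])
        rep = benchmark_dms(preds, dms)
        assert rep.spearman_abs == pytest.approx(1.0)
        assert rep.coverage == 1.0

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(77)
        preds = self._series(rng.random(1000))
        dms = self._series(rng.random(1000))
        assert benchmark_dms(preds, dms).spearman_abs < 0.1

    def test_constant_predictions_flagged(self):
        preds = self._series([0.5, 0.5, 0.5, 0.5])
        dms = self._series([0.1, 0.2, 0.3, 0.4])
        rep = benchmark_dms(preds, dms)
        assert rep.spearman_abs == 0.0
        assert rep.flags
        assert rep.mse == pytest.approx(np.mean(
            (np.array([0.5] * 4) - np.array([0.1, 0.2, 0.3, 0.4])) ** 2))

    def test_partial_overlap_coverage(self):
        preds = self._series([0.1, 0.2, 0.3, 0.4])
        dms = pd.Series([1.0, 0.9, 0.8, 0.7, 0.6],
                        index=["v0", "v1", "v2", "v9", "v8"])
        rep = benchmark_dms(preds, dms)
        assert rep.n_shared == 3
        assert rep.coverage == pytest.approx(3 / 5)

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match="3"):
            benchmark_dms(self._series([1.0, 2.0]), self._series([1.0, 2.0]))
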