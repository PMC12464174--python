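"""Confusion-matrix metrics, one-vs-rest collapse, AUC, model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seizurekit.evaluation import (
    BinaryCounts,
    compare_models,
    compute_metrics,
    confusion_counts,
    one_vs_rest_metrics,
    roc_auc,
)


class TestComputeMetrics:
    def test_hand_checked_matrix(self):
        """TP=90 FN=10 TN=80 FP=20, verified by direct arithmetic on the
        ratio definitions."""
        r = compute_metrics(BinaryCounts(TP=90, FN=10, TN=80, FP=20))
        assert r["SEN"] == pytest.approx(90.0, abs=5e-3)
        assert r["SPF"] == pytest.approx(80.0, abs=5e-3)
        assert r["ACC"] == pytest.approx(85.0, abs=5e-3)
        assert r["PPV"] == pytest.approx(81.8182, abs=5e-3)
        assert r["NPV"] == pytest.approx(88.8889, abs=5e-3)
        assert r["F1"] == pytest.approx(85.7143, abs=5e-3)
        assert r["MCC"] == pytest.approx(70.3526, abs=5e-3)

    def test_perfect_classifier(self):
        r = compute_metrics(BinaryCounts(TP=50, FN=0, TN=50, FP=0))
        for name in ("SEN", "SPF", "ACC", "PPV", "NPV", "MCC", "F1"):
            assert r[name] == pytest.approx(100.0)

    def test_symmetric_chance(self):
        r = compute_metrics(BinaryCounts(TP=25, FN=25, TN=25, FP=25))
        assert r["MCC"] == pytest.approx(0.0)
        assert r["ACC"] == pytest.approx(50.0)

    def test_zero_denominator_flagged_not_zeroed(self):
        r = compute_metrics(BinaryCounts(TP=0, FN=0, TN=10, FP=0))
        assert "SEN" in r.undefined and np.isnan(r["SEN"])
        assert r["ACC"] == pytest.approx(100.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(BinaryCounts(TP=0, FN=0, TN=0, FP=0))
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((2, 2), dtype=int))

    @given(
        tp=st.integers(1, 500),
        fn=st.integers(1, 500),
        tn=st.integers(1, 500),
        fp=st.integers(1, 500),
        scale=st.integers(2, 50),
    )
    def test_scale_invariance(self, tp, fn, tn, fp, scale):
        """Metrics are ratios: scaling all four counts changes nothing."""
        a = compute_metrics(BinaryCounts(tp, fn, tn, fp))
        b = compute_metrics(BinaryCounts(tp * scale, fn * scale, tn * scale, fp * scale))
        for name in a.values:
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    @given(tp=st.integers(1, 500), fn=st.integers(1, 500),
           tn=st.integers(1, 500), fp=st.integers(1, 500))
    def test_mcc_symmetric_under_class_swap(self, tp, fn, tn, fp):
        a = compute_metrics(BinaryCounts(tp, fn, tn, fp))
        b = compute_metrics(BinaryCounts(TP=tn, FN=fp, TN=tp, FP=fn))
        assert a["MCC"] == pytest.approx(b["MCC"], abs=1e-9)


class TestOneVsRest:
    def test_binary_collapse_equals_direct(self):
        cm = np.array([[80, 20], [10, 90]])
        direct = compute_metrics(cm)
        ovr = one_vs_rest_metrics(np.array([[80, 20], [10, 90]]))
        assert ovr.per_class[1]["SEN"] == pytest.approx(direct["SEN"])
        assert ovr.per_class[1]["PPV"] == pytest.approx(direct["PPV"])

    def test_diagonal_matrix_scores_100(self):
        r = one_vs_rest_metrics(np.diag([10, 20, 30]))
        for c in range(3):
            assert r.per_class[c]["ACC"] == pytest.approx(100.0)
            assert r.per_class[c]["MCC"] == pytest.approx(100.0)

    def test_3x3_against_explicit_tally(self):
        """Per-class values equal a brute-force per-class TP/FP/FN/TN count."""
        cm = np.array([[50, 3, 2], [4, 40, 6], [1, 5, 30]])
        r = one_vs_rest_metrics(cm)
        total = cm.sum()
        for c in range(3):
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = total - tp - fn - fp
            assert r.per_class[c]["SEN"] == pytest.approx(100 * tp / (tp + fn))
            assert r.per_class[c]["SPF"] == pytest.approx(100 * tn / (tn + fp))
            assert r.per_class[c]["PPV"] == pytest.approx(100 * tp / (tp + fp))
        # macro = unweighted mean over classes
        sens = [r.per_class[c]["SEN"] for c in range(3)]
        assert r["SEN"] == pytest.approx(np.mean(sens))


class TestConfusionCounts:
    def test_rows_true_columns_predicted(self):
        cm = confusion_counts([0, 0, 1, 1, 1], [0, 1, 1, 1, 0], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [1, 2]])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_tied_scores_half(self):
        assert roc_auc(np.array([0, 1, 0, 1]), np.full(4, 0.3)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.random.default_rng(0).random(5))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(200), 2)  # ties included
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, 50)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = r.random(50)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s)), abs=1e-12)


class TestCompareModels:
    def test_identical_vectors_degenerate(self):
        a = np.array([90.0, 91, 92, 93, 94, 95, 96, 97, 98, 99])
        r = compare_models(a, a.copy())
        assert r.degenerate
        assert r.wilcoxon_pvalue == 1.0
        assert np.isnan(r.t_pvalue)

    def test_constant_shift_flagged_infinite_d(self):
        a = np.array([90.0, 91, 92, 93, 94])
        r = compare_models(a + 1.0, a)
        assert r.degenerate
        assert np.isinf(r.cohens_d) and r.cohens_d > 0

    def test_cohens_d_closed_form(self):
        """Differences with mean 2 and sample SD 1 give d = 2 exactly."""
        b = np.array([80.0, 81, 82, 83, 84, 85, 86, 87, 88, 89])
        diff = np.array([2.0, 2, 2, 2, 2, 0.5, 3.5, 2, 2, 2])
        diff = 2.0 + (diff - diff.mean()) / diff.std(ddof=1)
        a = b + diff
        r = compare_models(a, b)
        assert r.cohens_d == pytest.approx(2.0, abs=0.01)
        assert r.mean_difference == pytest.approx(2.0, abs=1e-9)

    def test_agrees_with_scipy(self, rng):
        from scipy import stats

        a = rng.normal(95, 1, 10)
        b = rng.normal(93, 1, 10)
        r = compare_models(a, b)
        assert r.t_pvalue == pytest.approx(stats.ttest_rel(a, b).pvalue)
        assert r.wilcoxon_pvalue == pytest.approx(
            stats.wilcoxon(a, b, zero_method="wilcox").pvalue
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.ones(10), np.ones(9))

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.arange(4.0), np.arange(4.0))
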