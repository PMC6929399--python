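"""SVM training, grid search, stratified CV, and metric definitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from radonglau.classify import (
    GRID_EXPONENTS,
    EvalReport,
    SvmConfig,
    binarize_labels,
    compute_metrics,
    cross_validate,
    grid_search,
    train_svm,
)


def two_blobs(n=100, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 1.0, (n, 2)),
        rng.normal(sep, 1.0, (n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return X, y


def auc_pair_counting(scores, labels) -> float:
    """O(n^2) oracle: concordant pairs (+ half ties) / all pos-neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestTrainSvm:
    def test_separable_blobs_training_accuracy_100(self):
        X, y = two_blobs()
        model = train_svm(X, y, SvmConfig(sigma=2.0, C=10.0))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_wide_rbf_approaches_linear_decision(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        wide = train_svm(X, y, SvmConfig(sigma=1e4, C=1e4))
        lin = SVC(kernel="linear", C=1.0).fit(X, y)
        gx, gy = np.meshgrid(np.linspace(-3, 3, 25), np.linspace(-3, 3, 25))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        assert np.mean(wide.predict(grid) == lin.predict(grid)) >= 0.95

    def test_deterministic_given_identical_data(self):
        X, y = two_blobs(n=40, sep=3.0)
        a = train_svm(X, y).decision_function(X)
        b = train_svm(X, y).decision_function(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.random.default_rng(0).random((10, 2)), np.zeros(10))

    def test_string_labels_accepted(self):
        X, y = two_blobs(n=20, sep=8.0)
        labels = np.where(y == 1, "glaucoma", "Normal")
        model = train_svm(X, labels, SvmConfig(sigma=2.0, C=10.0))
        assert np.mean(model.predict(X) == y) == 1.0


class TestGridSearch:
    def test_grid_arithmetic(self):
        # 2^-10 .. 2^10 in steps of 2^0.5: 41 exponents, 1681 (C, sigma) pairs
        assert len(GRID_EXPONENTS) == 41
        assert GRID_EXPONENTS[0] == -10.0 and GRID_EXPONENTS[-1] == 10.0
        assert len(GRID_EXPONENTS) * len(GRID_EXPONENTS) == 1681

    def test_degenerate_single_pair(self):
        X, y = two_blobs(n=20)
        cfg = SvmConfig(grid_exponents=(2.0,))
        assert grid_search(X, y, cfg, folds=2) == (4.0, 4.0)

    def test_best_beats_grid_corners(self):
        X, y = two_blobs(n=15, sep=3.0, seed=1)
        cfg = SvmConfig(grid_exponents=(-10.0, -5.0, 0.0, 5.0, 10.0))
        folds, seed = 3, 0

        def cv_acc(C, sigma):
            splits = StratifiedKFold(folds, shuffle=True, random_state=seed).split(X, y)
            correct = 0
            for tr, te in splits:
                m = train_svm(X[tr], y[tr], SvmConfig(C=C, sigma=sigma))
                correct += np.sum(m.predict(X[te]) == y[te])
            return correct / len(y)

        C, sigma = grid_search(X, y, cfg, folds=folds, seed=seed)
        best = cv_acc(C, sigma)
        for ce in (-10.0, 10.0):
            for se in (-10.0, 10.0):
                assert best >= cv_acc(2.0**ce, 2.0**se) - 1e-12

    def test_fold_count_validation(self):
        X, y = two_blobs(n=4)
        with pytest.raises(ValueError):
            grid_search(X, y, SvmConfig(), folds=10)
        with pytest.raises(ValueError):
            grid_search(X, y, SvmConfig(), folds=1)


class TestComputeMetrics:
    def test_printed_formula_on_toy_counts(self):
        m = compute_metrics(tp=2, tn=3, fp=1, fn=0)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.75
        assert m["accuracy"] == pytest.approx(5 / 6)

    def test_all_correct_balanced(self):
        scores = np.array([-1.0] * 10 + [1.0] * 10)
        labels = np.array([0] * 10 + [1] * 10)
        m = compute_metrics(10, 10, 0, 0, scores=scores, labels=labels)
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0

    def test_auc_matches_pair_counting_oracle(self):
        scores = np.array([0.2, 0.8, 0.4, 0.4, 0.9, 0.1])
        labels = np.array([0, 1, 1, 0, 1, 0])
        m = compute_metrics(0, 0, 3, 3, scores=scores, labels=labels)
        assert m["auc"] == pytest.approx(auc_pair_counting(scores, labels))

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_auc_oracle_and_monotone_invariance(self, raw):
        # round so the tie structure survives exp() in floating point
        scores = np.round(np.array(raw), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        m1 = compute_metrics(1, 1, 0, 0, scores=scores, labels=labels)
        assert m1["auc"] == pytest.approx(auc_pair_counting(scores, labels))
        m2 = compute_metrics(1, 1, 0, 0, scores=np.exp(scores / 3.0), labels=labels)
        assert m2["auc"] == pytest.approx(m1["auc"])

    def test_zero_denominator_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = compute_metrics(0, 5, 0, 0)
        assert np.isnan(m["sensitivity"]) and m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 0)


class TestBinarize:
    def test_canonical_and_case_variant_labels(self):
        out = binarize_labels(["normal", "Glaucoma", " GLAUCOMA ", 0, 1, True])
        np.testing.assert_array_equal(out, [0, 1, 1, 0, 1, 1])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            binarize_labels(["suspect"])


class TestCrossValidate:
    def test_stratification_contract(self):
        X, y = two_blobs(n=52, sep=2.0)
        rep = cross_validate(X, y, SvmConfig(sigma=3.0), k=10, seed=1)
        sizes = [f["tp"] + f["tn"] + f["fp"] + f["fn"] for f in rep.per_fold]
        assert max(sizes) - min(sizes) <= 1
        pos = [f["tp"] + f["fn"] for f in rep.per_fold]
        assert max(pos) - min(pos) <= 1
        # confusion counts consistent with fold accuracy on every fold
        for f in rep.per_fold:
            assert f["accuracy"] == pytest.approx(
                (f["tp"] + f["tn"]) / (f["tp"] + f["tn"] + f["fp"] + f["fn"])
            )

    def test_bit_stable_under_fixed_seed(self):
        X, y = two_blobs(n=30, sep=3.0)
        a = cross_validate(X, y, SvmConfig(sigma=3.0), k=5, seed=7)
        b = cross_validate(X, y, SvmConfig(sigma=3.0), k=5, seed=7)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_separable_blobs_near_perfect(self):
        X, y = two_blobs(n=40, sep=8.0)
        rep = cross_validate(X, y, SvmConfig(sigma=3.0, C=10.0), k=5, seed=0)
        assert rep.aggregate["accuracy_pct"] >= 95.0
        assert rep.aggregate["auc"] >= 0.99

    def test_noise_features_near_chance(self):
        """Permutation-style null: pure noise features give ~50% accuracy."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 10))
        y = np.array([0, 1] * 40)
        rep = cross_validate(X, y, SvmConfig(sigma=3.0), k=5, seed=0)
        se = 100.0 * np.sqrt(0.25 / 80)
        assert abs(rep.aggregate["accuracy_pct"] - 50.0) <= 3 * se

    def test_report_structure(self):
        X, y = two_blobs(n=25, sep=4.0)
        rep = cross_validate(X, y, SvmConfig(sigma=3.0), k=5, seed=0)
        assert isinstance(rep, EvalReport)
        assert len(rep.per_fold) == 5
        agg = rep.aggregate
        assert agg["tp"] + agg["tn"] + agg["fp"] + agg["fn"] == 50
        assert 0.0 <= agg["auc"] <= 1.0
        # pooled accuracy consistent with pooled confusion counts
        assert agg["accuracy_pct"] == pytest.approx(
            100.0 * (agg["tp"] + agg["tn"]) / 50
        )

    def test_k_validation(self):
        X, y = two_blobs(n=5)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=1)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=6)


def test_sigma_gamma_conversion():
    cfg = SvmConfig(sigma=2.0)
    assert cfg.gamma == pytest.approx(1.0 / 8.0)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SvmConfig(kernel="sigmoid")
    with pytest.raises(ValueError):
        SvmConfig(C=-1.0)
    with pytest.raises(ValueError):
        SvmConfig(grid_exponents=(1.0, 0.0))
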