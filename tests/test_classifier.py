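"""SVM training/prediction, performance metrics and CV protocols."""

import math

import numpy as np
import pytest

from texdirect import (Metrics, SVMConfig, SVMModel, ValidationError,
                       compute_metrics, cross_validate, polynomial_kernel,
                       train_svm)
from texdirect.classifier import make_folds


@pytest.mark.parametrize("x,xi,d,expected", [
    ([0.0, 0.0], [0.0, 0.0], 2, 1.0),
    ([1.0, 2.0], [3.0, 4.0], 2, 144.0),
    ([1.0, 2.0], [3.0, 4.0], 1, 12.0),
])
def test_polynomial_kernel_hand_values(x, xi, d, expected):
    assert polynomial_kernel(x, xi, d) == expected


def test_kernel_symmetry(rng):
    for _ in range(20):
        a, b = rng.normal(size=(2, 5))
        assert polynomial_kernel(a, b) == pytest.approx(polynomial_kernel(b, a))


def test_gram_matrix_is_psd(rng):
    for _ in range(5):
        X = rng.normal(size=(12, 3))
        gram = (X @ X.T + 1.0) ** 2
        eigvals = np.linalg.eigvalsh(gram)
        assert eigvals.min() >= -1e-8


def test_xor_is_separated_by_degree_two():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([-1, -1, 1, 1])
    model = train_svm(X, y, SVMConfig(degree=2, C=10.0))
    assert np.array_equal(model.predict(X), y)
    assert model.predict(np.array([0.9, 0.1])) == 1


def test_linearly_separable_toy_set():
    # two points per class straddling x2 = 0 with geometric margin 2
    X = np.array([[0.0, 1.0], [1.0, 1.0], [0.0, -1.0], [1.0, -1.0]])
    y = np.array([1, 1, -1, -1])
    model = train_svm(X, y, SVMConfig(degree=1, C=100.0))
    assert np.array_equal(model.predict(X), y)
    assert len(model.dual_coefs) <= 3


def test_duplicated_data_leaves_decision_unchanged(rng):
    X = rng.normal(size=(12, 2))
    y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[0]
    m1 = train_svm(X, y)
    m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]))
    probe = rng.normal(size=(25, 2))
    np.testing.assert_allclose(m1.decision_function(probe),
                               m2.decision_function(probe), atol=1e-6)


def test_tie_decision_maps_to_abnormal():
    model = SVMModel(support_vectors=np.array([[1.0, 0.0]]),
                     dual_coefs=np.array([0.0]), bias=0.0, config=SVMConfig())
    assert model.predict(np.array([5.0, 5.0])) == 1


def test_support_vectors_keep_their_labels():
    X = np.array([[0.0, 1.0], [0.2, 1.1], [0.0, -1.0], [0.3, -0.9]])
    y = np.array([1, 1, -1, -1])
    model = train_svm(X, y, SVMConfig(degree=2, C=1000.0))
    for sv in model.support_vectors:
        idx = np.argmin(np.abs(X - sv).sum(axis=1))
        assert model.predict(sv) == y[idx]


@pytest.mark.parametrize("predicted,truth,expected", [
    ([1, 1, -1, -1], [1, 1, -1, -1], (1.0, 1.0, 1.0)),
    ([1, -1, -1, -1], [1, 1, -1, -1], (0.75, 0.5, 1.0)),
    ([1, 1, 1, 1], [1, 1, -1, -1], (0.5, 1.0, 0.0)),
])
def test_compute_metrics_hand_counts(predicted, truth, expected):
    got = compute_metrics(predicted, truth)
    assert got.as_tuple() == pytest.approx(expected)


def test_absent_class_yields_nan_not_crash():
    got = compute_metrics([1, 1], [1, 1])
    assert got.sensitivity == 1.0
    assert math.isnan(got.specificity)


def test_label_flip_swaps_sensitivity_specificity(rng):
    truth = rng.choice([-1, 1], size=40)
    truth[:2] = [1, -1]  # both classes present
    predicted = rng.choice([-1, 1], size=40)
    m = compute_metrics(predicted, truth)
    flipped = compute_metrics(-predicted, -truth)
    assert flipped.sensitivity == pytest.approx(m.specificity)
    assert flipped.specificity == pytest.approx(m.sensitivity)


def _toy_problem(n=50, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, 2))
    y = np.concatenate([np.ones(n, int), -np.ones(n, int)])
    X[:n] += 1.5
    return X, y


def test_ccr_identity_on_pooled_report():
    X, y = _toy_problem()
    report = cross_validate(X, y, protocol="tenfold", seed=1)
    o = report.overall
    n_pos, n_neg = (y == 1).sum(), (y == -1).sum()
    assert o.ccr == pytest.approx(
        (o.sensitivity * n_pos + o.specificity * n_neg) / (n_pos + n_neg))


def test_loocv_performs_n_evaluations():
    X, y = _toy_problem(n=6)
    report = cross_validate(X, y, protocol="loocv", seed=0)
    assert report.n_folds == 12
    assert all(m.ccr in (0.0, 1.0) for m in report.per_fold)


def test_tenfold_partitions_100_samples():
    X, y = _toy_problem(n=50)
    folds = make_folds(y, "tenfold", seed=3)
    sizes = sorted(len(f) for f in folds)
    assert sizes == [10] * 10
    all_idx = np.concatenate(folds)
    assert len(all_idx) == 100 and len(set(all_idx)) == 100


def test_stratified_folds_respect_class_ratio():
    X, y = _toy_problem(n=50)
    for fold in make_folds(y, "tenfold", seed=3):
        assert abs((y[fold] == 1).sum() - 5) <= 1


def test_fixed_seed_reports_are_identical():
    X, y = _toy_problem()
    r1 = cross_validate(X, y, protocol="tenfold", seed=7)
    r2 = cross_validate(X, y, protocol="tenfold", seed=7)
    np.testing.assert_array_equal(r1.predictions, r2.predictions)
    np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
    assert r1.per_fold == r2.per_fold


def test_different_seeds_shuffle_folds():
    X, y = _toy_problem()
    r1 = cross_validate(X, y, protocol="tenfold", seed=1)
    r2 = cross_validate(X, y, protocol="tenfold", seed=2)
    assert not np.array_equal(r1.fold_assignments, r2.fold_assignments)


def test_report_summary_schema():
    X, y = _toy_problem()
    summary = cross_validate(X, y, seed=0).summary_dict()
    for key in ("protocol", "seed", "C", "degree", "ccr_mean", "ccr_sd",
                "sensitivity_mean", "specificity_overall"):
        assert key in summary


def test_validation_errors(rng):
    with pytest.raises(ValidationError):
        train_svm(np.ones((4, 2)), np.ones(4, int))  # single class
    with pytest.raises(ValidationError):
        train_svm(np.full((4, 2), np.nan), np.array([1, 1, -1, -1]))
    with pytest.raises(ValidationError):
        polynomial_kernel([1.0], [1.0, 2.0])
    with pytest.raises(ValidationError):
        compute_metrics([1, 1], [1])
    X = rng.normal(size=(8, 2))
    y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
    with pytest.raises(ValidationError):
        cross_validate(X, y, protocol="tenfold", seed=0)  # < 10 per class
    with pytest.raises(ValidationError):
        make_folds(y, "fivefold", seed=0)
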