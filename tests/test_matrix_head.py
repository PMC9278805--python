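"""Nuclear norm, its subgradient, the hinge objective and prediction."""

import numpy as np
import pytest

from nrdnn import (
    MatrixClassifier,
    hinge_loss,
    nuclear_norm,
    nuclear_subgradient,
    objective,
    objective_gradients,
    predict,
)
from nrdnn.exceptions import ConfigError, DataError, ShapeError

from conftest import central_difference, relative_error


def test_nuclear_norm_known_values():
    assert nuclear_norm(np.eye(3)) == pytest.approx(3.0)
    assert nuclear_norm(np.diag([3.0, 4.0])) == pytest.approx(7.0)


def test_nuclear_norm_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        W = rng.normal(size=(4, 6))
        expected = np.sqrt(np.maximum(np.linalg.eigvalsh(W @ W.T), 0.0)).sum()
        assert abs(nuclear_norm(W) - expected) < 1e-8


def test_subgradient_at_orthonormal_rows_is_the_matrix():
    rng = np.random.default_rng(1)
    Q, _ = np.linalg.qr(rng.normal(size=(5, 3)))
    W = Q.T  # 3 x 5 with orthonormal rows, all singular values 1
    np.testing.assert_allclose(nuclear_subgradient(W), W, atol=1e-12)


def test_subgradient_matches_numeric_gradient_at_full_rank():
    rng = np.random.default_rng(2)
    W = rng.normal(size=(3, 5))
    g = nuclear_subgradient(W)
    num = central_difference(lambda: nuclear_norm(W), W)
    assert relative_error(g, num, floor=1e-4) < 1e-5


def test_subgradient_of_zero_is_zero_and_norm_bound():
    np.testing.assert_array_equal(nuclear_subgradient(np.zeros((3, 4))), 0.0)
    rng = np.random.default_rng(3)
    W = rng.normal(size=(4, 7))
    g = nuclear_subgradient(W)
    rank = np.linalg.matrix_rank(W)
    assert np.linalg.norm(g) <= np.sqrt(rank) + 1e-12


def test_hinge_loss_cases():
    clf = MatrixClassifier(W=np.eye(2), b=0.0)
    Z = np.eye(2)  # trace(W^T Z) = 2
    assert hinge_loss(Z, 1, clf) == pytest.approx(0.0)
    clf_b = MatrixClassifier(W=np.zeros((2, 2)), b=0.0)
    assert hinge_loss(Z, 1, clf_b) == pytest.approx(1.0)
    clf_half = MatrixClassifier(W=np.zeros((2, 2)), b=0.5)
    assert hinge_loss(Z, -1, clf_half) == pytest.approx(1.5)
    with pytest.raises(DataError):
        hinge_loss(Z, 0, clf)


def test_objective_hand_arithmetic():
    """1-sample toy: 0.5*2 + 0.1*2 + max(0, 1-2) = 1.2."""
    clf = MatrixClassifier(W=np.eye(2), b=0.0, C=1.0, tau=0.1)
    assert objective([(np.eye(2), 1)], clf) == pytest.approx(1.2)


def test_objective_zero_model_is_C_times_N():
    clf = MatrixClassifier(W=np.zeros((3, 4)), b=0.0, C=2.5, tau=0.3)
    batch = [(np.ones((3, 4)), 1), (np.ones((3, 4)), -1), (np.zeros((3, 4)), 1)]
    assert objective(batch, clf) == pytest.approx(2.5 * 3)


def test_objective_monotone_in_C_and_tau():
    rng = np.random.default_rng(4)
    W = rng.normal(size=(3, 4))
    batch = [(rng.normal(size=(3, 4)), 1), (rng.normal(size=(3, 4)), -1)]
    vals = [objective(batch, MatrixClassifier(W=W, C=C, tau=tau))
            for C, tau in [(0.5, 0.0), (0.5, 0.2), (1.5, 0.2), (1.5, 1.0)]]
    assert vals == sorted(vals)


def test_objective_gradients_match_central_differences():
    rng = np.random.default_rng(5)
    W = rng.normal(size=(3, 4))
    clf = MatrixClassifier(W=W, b=0.3, C=0.7, tau=0.2)
    batch = [(rng.normal(size=(3, 4)), 1 if i % 2 else -1) for i in range(5)]
    gW, gb = objective_gradients(batch, clf)
    numW = central_difference(lambda: objective(batch, clf), clf.W)
    assert relative_error(gW, numW, floor=1e-4) < 1e-5

    def value_b():
        return objective(batch, MatrixClassifier(W=W, b=clf.b, C=0.7, tau=0.2))

    eps = 1e-6
    clf.b += eps
    fp = objective(batch, clf)
    clf.b -= 2 * eps
    fm = objective(batch, clf)
    clf.b += eps
    assert abs((fp - fm) / (2 * eps) - gb) < 1e-6


def test_inactive_hinges_leave_only_regularizer_gradient():
    rng = np.random.default_rng(6)
    W = rng.normal(size=(2, 3)) * 0.1
    clf = MatrixClassifier(W=W, b=0.0, C=1.0, tau=0.5)
    # samples far beyond the margin: y * score >> 1
    big = W / np.sum(W * W) * 10.0
    batch = [(big, 1), (-big, -1)]
    gW, gb = objective_gradients(batch, clf)
    np.testing.assert_allclose(gW, W + 0.5 * nuclear_subgradient(W), atol=1e-12)
    assert gb == 0.0


def test_tau_zero_equals_vectorized_frobenius_hinge_model():
    """With tau=0 the matrix gradient equals the vectorized linear one."""
    rng = np.random.default_rng(7)
    W = rng.normal(size=(3, 4))
    clf = MatrixClassifier(W=W, b=0.1, C=1.3, tau=0.0)
    batch = [(rng.normal(size=(3, 4)), 1 if i % 2 else -1) for i in range(6)]
    gW, gb = objective_gradients(batch, clf)
    # independent vectorized implementation
    w = W.ravel()
    gw_vec = w.copy()
    gb_vec = 0.0
    for Z, y in batch:
        margin = 1.0 - y * (w @ Z.ravel() + clf.b)
        if margin > 0:
            gw_vec -= clf.C * y * Z.ravel()
            gb_vec -= clf.C * y
    np.testing.assert_allclose(gW.ravel(), gw_vec, atol=1e-12)
    assert gb == pytest.approx(gb_vec)


def test_trace_inner_product_identity():
    rng = np.random.default_rng(8)
    for _ in range(10):
        W = rng.normal(size=(4, 5))
        Z = rng.normal(size=(4, 5))
        assert np.trace(W.T @ Z) == pytest.approx(W.ravel() @ Z.ravel())


def test_predict_rule_and_tie_break():
    clf = MatrixClassifier(W=np.array([[1.0, 0.0], [0.0, 2.0]]), b=1.0)
    score, label = predict(np.array([[3.0, 0.0], [0.0, 4.0]]), clf)
    assert score == pytest.approx(12.0)
    assert label == 1
    zero_clf = MatrixClassifier(W=np.zeros((2, 2)), b=0.0)
    score, label = predict(np.ones((2, 2)), zero_clf)
    assert score == 0.0 and label == 1  # boundary goes positive
    const_clf = MatrixClassifier(W=np.zeros((2, 2)), b=-0.5)
    assert predict(np.eye(2), const_clf) == (-0.5, -1)


def test_shape_and_config_validation():
    clf = MatrixClassifier(W=np.zeros((2, 2)))
    with pytest.raises(ShapeError):
        predict(np.zeros((3, 2)), clf)
    with pytest.raises(ConfigError):
        MatrixClassifier(W=np.zeros((2, 2)), C=0.0)
    with pytest.raises(ConfigError):
        MatrixClassifier(W=np.zeros((2, 2)), tau=-0.1)
    with pytest.raises(DataError):
        objective([], clf)


def test_full_batch_subgradient_descent_decreases_objective():
    """Fixed small steps go downhill (<= 2 % uphill tolerance)."""
    rng = np.random.default_rng(9)
    clf = MatrixClassifier(W=rng.normal(size=(3, 4)), b=0.0, C=1.0, tau=0.3)
    batch = [(rng.normal(size=(3, 4)), 1 if i % 2 else -1) for i in range(8)]
    values = [objective(batch, clf)]
    for _ in range(200):
        gW, gb = objective_gradients(batch, clf)
        clf.W = clf.W - 1e-3 * gW
        clf.b = clf.b - 1e-3 * gb
        values.append(objective(batch, clf))
    diffs = np.diff(values)
    assert np.mean(diffs > 1e-12) <= 0.02
    assert values[-1] < values[0]
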