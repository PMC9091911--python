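import numpy as np
import pytest

from conftest import random_orthonormal_rows
from lmadapt.alignment import (
    alignment_matrix,
    class_indicators,
    graph_adjacency,
    graph_laplacian,
    lambda_matrix,
    mmd_indicator,
    mmd_statistic,
)
from lmadapt.types import DomainError, encode_one_hot


def test_mmd_indicator_one_one():
    assert np.array_equal(mmd_indicator(1, 1), [[1, -1], [-1, 1]])


def test_mmd_indicator_two_one():
    expected = np.array([
        [0.25, 0.25, -0.5],
        [0.25, 0.25, -0.5],
        [-0.5, -0.5, 1.0],
    ])
    D = mmd_indicator(2, 1)
    assert np.allclose(D, expected)
    assert abs(D.sum()) < 1e-12


@pytest.mark.parametrize("n_a, n_t", [(3, 5), (7, 2), (10, 10)])
def test_mmd_indicator_entries_sum_to_zero(n_a, n_t):
    assert abs(mmd_indicator(n_a, n_t).sum()) < 1e-12


def test_mmd_indicator_member_sets():
    D = mmd_indicator(3, 2, members_a=[0, 2], members_t=[3], N=5)
    assert np.isclose(D[0, 0], 0.25) and np.isclose(D[3, 3], 1.0)
    assert np.isclose(D[0, 3], -0.5)
    assert D[1].sum() == 0 and D[4].sum() == 0  # non-members untouched
    assert abs(D.sum()) < 1e-12


def test_mmd_indicator_overlapping_members_rejected():
    with pytest.raises(DomainError):
        mmd_indicator(3, 2, members_a=[0, 3], members_t=[3], N=5)


def test_mmd_indicator_empty_class_gives_zero_matrix():
    D = mmd_indicator(3, 2, members_a=[], members_t=[3, 4], N=5)
    assert np.all(D == 0)


def test_trace_path_equals_mean_embedding(rng):
    """trace(X D X^T) must equal the direct mean-difference computation."""
    Xs = rng.standard_normal((3, 7))
    Xt = rng.standard_normal((3, 5))
    X = np.hstack([Xs, Xt])
    D = mmd_indicator(7, 5)
    assert np.isclose(
        np.trace(X @ D @ X.T), mmd_statistic(Xs, Xt), atol=1e-12
    )
    Theta = random_orthonormal_rows(rng, 2, 3)
    assert np.isclose(
        np.trace(Theta @ X @ D @ X.T @ Theta.T),
        mmd_statistic(Xs, Xt, Theta),
        atol=1e-12,
    )


def test_mmd_statistic_trivial_cases(rng):
    X = rng.standard_normal((4, 6))
    assert mmd_statistic(X, X) == 0.0
    v = np.array([1.0, -2.0, 0.5, 3.0])
    assert np.isclose(mmd_statistic(X + v[:, None], X), v @ v)


def test_mmd_quadratic_form_translation_invariant(rng):
    X = rng.standard_normal((3, 9))
    D = mmd_indicator(4, 5)
    shift = rng.standard_normal(3)
    Xs = X + shift[:, None]
    assert np.isclose(np.trace(X @ D @ X.T), np.trace(Xs @ D @ Xs.T))


def test_lambda_single_class_doubles_marginal(rng):
    X = rng.standard_normal((3, 6))
    Ys = np.ones((4, 1))
    Yt = np.ones((2, 1))
    D = mmd_indicator(4, 2)
    assert np.allclose(lambda_matrix(X, Ys, Yt), 2 * X @ D @ X.T)


def test_lambda_vanishes_for_identical_domains(rng):
    """Identical per-class samples on both sides give zero alignment cost."""
    Xsrc = rng.standard_normal((4, 9))
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    X = np.hstack([Xsrc, Xsrc])
    Y = encode_one_hot(labels, 3).values
    Lam = lambda_matrix(X, Y, Y)
    Theta = random_orthonormal_rows(rng, 2, 4)
    assert abs(np.trace(Theta @ Lam @ Theta.T)) < 1e-10


def test_empty_target_class_contributes_zero(rng):
    Ys = encode_one_hot([1, 2, 3], 3).values
    Yt = encode_one_hot([1, 2], 3).values  # class 3 empty on target
    Ds = class_indicators(3, 2, Ys, Yt)
    assert np.all(Ds[2] == 0)
    assert not np.all(Ds[0] == 0)


def test_adjacency_coincident_points_weight_one():
    X = np.zeros((2, 2))
    W = graph_adjacency(X, k=1, gamma=1.0)
    assert np.isclose(W[0, 1], 1.0) and W[0, 0] == 0


def test_adjacency_collinear_points():
    X = np.array([[0.0, 1.0, 10.0]])
    W = graph_adjacency(X, k=1, gamma=1.0)
    assert np.isclose(W[0, 1], np.exp(-1.0))
    assert np.isclose(W[1, 2], np.exp(-81.0))
    assert W[0, 2] == 0.0


def test_adjacency_structure_random(rng):
    X = rng.standard_normal((4, 25))
    k = 3
    W = graph_adjacency(X, k=k, gamma="auto", n_classes=2)
    assert np.allclose(W, W.T)
    assert np.all(np.diag(W) == 0)
    assert np.all((W > 0).sum(axis=1) >= k)


def test_adjacency_supervised_drops_cross_label_edges(rng):
    X = rng.standard_normal((3, 12))
    labels = np.repeat([0, 1], 6)
    W = graph_adjacency(X, labels=labels, k=5, gamma=1.0)
    same = labels[:, None] == labels[None, :]
    assert np.all(W[~same] == 0)


def test_adjacency_k_too_large_rejected(rng):
    with pytest.raises(DomainError):
        graph_adjacency(rng.standard_normal((2, 4)), k=4, gamma=1.0)


def test_laplacian_two_nodes():
    assert np.array_equal(
        graph_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]])),
        [[1, -1], [-1, 1]],
    )


def test_laplacian_zero_adjacency():
    assert np.all(graph_laplacian(np.zeros((3, 3))) == 0)


def test_laplacian_rejects_asymmetry():
    with pytest.raises(DomainError):
        graph_laplacian(np.array([[0.0, 1.0], [0.0, 0.0]]))


def test_laplacian_psd_and_quadratic_form(rng):
    W = rng.uniform(0, 1, (8, 8))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    L = graph_laplacian(W)
    assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)
    assert np.linalg.eigvalsh(L).min() >= -1e-10
    x = rng.standard_normal(8)
    brute = 0.5 * sum(
        W[i, j] * (x[i] - x[j]) ** 2 for i in range(8) for j in range(8)
    )
    assert np.isclose(x @ L @ x, brute, atol=1e-9)


def test_alignment_matrix_components(rng):
    Xs = rng.standard_normal((3, 8))
    Xt = rng.standard_normal((3, 6))
    X = np.hstack([Xs, Xt])
    Ys = encode_one_hot(rng.integers(1, 3, 8), 2).values
    Yt = encode_one_hot(rng.integers(1, 3, 6), 2).values
    ops = alignment_matrix(X, Ys, Yt, k=3, gamma=1.0)
    assert np.allclose(ops.C, ops.C.T)
    assert np.allclose(ops.C - ops.Lambda, X @ ops.L @ X.T, atol=1e-10)
    Theta = random_orthonormal_rows(rng, 2, 3)
    assert np.trace(Theta @ ops.C @ Theta.T) >= -1e-10


def test_alignment_matrix_single_sample_domains():
    X = np.array([[1.0, 2.0], [0.0, 1.0]])
    Ys = np.array([[1.0, 0.0]])
    Yt = np.array([[1.0, 0.0]])
    ops = alignment_matrix(X, Ys, Yt, k=1, gamma=1.0)
    assert ops.C.shape == (2, 2)
    assert np.all(np.isfinite(ops.C))
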