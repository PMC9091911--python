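"""Distribution-alignment operators for each source-target pair.

For a pair X = [X_src, X_tgt] (d x N, N = n_a + n_t) the module builds

* the marginal MMD indicator ``D`` with ``trace(X D X^T)`` equal to the
  squared distance of the two sample means,
* one class-conditional indicator per class (target membership from
  pseudo-labels), summed with the marginal term into the aggregate ``Lambda``,
* a k-nearest-neighbor heat-kernel adjacency and its graph Laplacian ``L``,
* the combined alignment matrix ``C = X L X^T + Lambda`` whose quadratic form
  ``trace(Theta C Theta^T)`` the optimizer minimizes over the latent subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .types import DomainError, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class AlignmentOperators:
    """All alignment operators of one source-target pair."""

    L: np.ndarray          # N x N graph Laplacian of the pair
    D: np.ndarray          # N x N marginal MMD indicator
    D_class: List[np.ndarray]   # c class-conditional indicators
    Lambda: np.ndarray     # aggregate alignment matrix (d x d in linear mode)
    C: np.ndarray          # X L X^T + Lambda


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def mmd_indicator(
    n_a: int,
    n_t: int,
    members_a: Optional[np.ndarray] = None,
    members_t: Optional[np.ndarray] = None,
    N: Optional[int] = None,
) -> np.ndarray:
    """MMD indicator matrix for a source of size n_a and target of size n_t.

    Without member sets this is the marginal indicator: ``1/n_a^2`` among the
    first ``n_a`` indices, ``1/n_t^2`` among the last ``n_t``, and
    ``-1/(n_a n_t)`` across. With member sets (class-conditional variant) the
    same pattern is embedded at the given indices inside an ``N x N`` zero
    matrix, with the counts taken from the member sets. Empty membership on
    either side returns the zero matrix (logged skip).
    """
    if N is None:
        N = n_a + n_t
    if members_a is None and members_t is None:
        if n_a < 1 or n_t < 1:
            raise DomainError("n_a and n_t must be at least 1")
        if N != n_a + n_t:
            raise DomainError("N must equal n_a + n_t without member sets")
        members_a = np.arange(n_a)
        members_t = np.arange(n_a, N)
    else:
        members_a = np.asarray([] if members_a is None else members_a, int)
        members_t = np.asarray([] if members_t is None else members_t, int)
        if members_a.size and (members_a.min() < 0 or members_a.max() >= n_a):
            raise DomainError("members_a must index the source range")
        if members_t.size and (
            members_t.min() < n_a or members_t.max() >= n_a + n_t
        ):
            raise DomainError("members_t must index the target range")
        if np.intersect1d(members_a, members_t).size:
            raise DomainError("member sets overlap")
        if members_a.size == 0 or members_t.size == 0:
            logger.debug(
                "mmd_indicator: empty class on one side (|a|=%d, |t|=%d), "
                "returning zero matrix", members_a.size, members_t.size,
            )
            return np.zeros((N, N))
    ka, kt = len(members_a), len(members_t)
    D = np.zeros((N, N))
    D[np.ix_(members_a, members_a)] = 1.0 / ka**2
    D[np.ix_(members_t, members_t)] = 1.0 / kt**2
    D[np.ix_(members_a, members_t)] = -1.0 / (ka * kt)
    D[np.ix_(members_t, members_a)] = -1.0 / (ka * kt)
    return D


def mmd_statistic(X_src, X_tgt, Theta: Optional[np.ndarray] = None) -> float:
    """Squared norm of the difference of (projected) sample means.

    Direct mean-embedding computation of the squared linear-kernel MMD; the
    independent oracle for the indicator-matrix path
    ``trace(Theta X D X^T Theta^T)``.
    """
    Xs, Xt = _values(X_src), _values(X_tgt)
    if Xs.shape[0] != Xt.shape[0]:
        raise DomainError("feature dimensions differ")
    diff = Xs.mean(axis=1) - Xt.mean(axis=1)
    if Theta is not None:
        diff = Theta @ diff
    return float(diff @ diff)


def resolve_gamma(X, gamma, n_classes: int = 1) -> float:
    """Resolve the heat-kernel width; "auto" uses sqrt(mean ||x_i||_2) / c."""
    if gamma != "auto":
        g = float(gamma)
        if g <= 0:
            raise DomainError("gamma must be positive")
        return g
    Xv = _values(X)
    theta_bar = float(np.sqrt(np.mean(np.linalg.norm(Xv, axis=0))))
    return max(theta_bar / max(n_classes, 1), np.finfo(float).tiny)


def graph_adjacency(
    X,
    labels: Optional[np.ndarray] = None,
    k: int = 5,
    gamma="auto",
    n_classes: int = 1,
) -> np.ndarray:
    """Symmetrized k-nearest-neighbor heat-kernel adjacency.

    Entry (i, j) is ``exp(-gamma ||x_i - x_j||^2)`` when i is among the k
    nearest neighbors of j or vice versa, 0 otherwise; the diagonal is zero.
    When ``labels`` are given (supervised variant) edges between
    differently-labeled nodes are dropped.
    """
    Xv = _values(X)
    N = Xv.shape[1]
    if k >= N:
        raise DomainError(f"k = {k} must be smaller than the node count {N}")
    g = resolve_gamma(Xv, gamma, n_classes)
    diff = Xv.T[:, None, :] - Xv.T[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # k nearest neighbors of each column (self excluded, stable ties)
    d2_noself = d2 + np.diag(np.full(N, np.inf))
    nbr = np.argsort(d2_noself, axis=1, kind="stable")[:, :k]
    conn = np.zeros((N, N), dtype=bool)
    conn[np.arange(N)[:, None], nbr] = True
    mask = conn | conn.T
    W = np.where(mask, np.exp(-g * d2), 0.0)
    if labels is not None:
        lab = np.asarray(labels)
        same = lab[:, None] == lab[None, :]
        W = np.where(same, W, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def graph_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian L = diag(row sums) - adjacency."""
    W = np.asarray(adjacency, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise DomainError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise DomainError("adjacency must be symmetric")
    if np.any(W < 0):
        raise DomainError("adjacency must be nonnegative")
    return np.diag(W.sum(axis=1)) - W


def lambda_matrix(
    X_pair,
    Y_src: np.ndarray,
    Y_tgt: np.ndarray,
) -> np.ndarray:
    """Aggregate MMD alignment matrix Lambda = sum_{l=0..c} X D^(l) X^T.

    ``l = 0`` is the marginal indicator; classes l = 1..c use the source
    label indicator and the current (hard pseudo-label) target indicator.
    Classes empty on either side contribute zero. ``X_pair`` is the packed
    d x N pair [X_src, X_tgt]; in kernel mode pass the kernel-mapped pair.
    """
    X = _values(X_pair)
    Ys = np.asarray(Y_src, float)
    Yt = np.asarray(Y_tgt, float)
    n_a, n_t = Ys.shape[0], Yt.shape[0]
    N = n_a + n_t
    if X.shape[1] != N:
        raise DomainError("X_pair column count must equal n_src + n_tgt")
    if Ys.shape[1] != Yt.shape[1]:
        raise DomainError("source/target class counts differ")
    c = Ys.shape[1]
    D_total = mmd_indicator(n_a, n_t)
    for l in range(c):
        members_a = np.flatnonzero(Ys[:, l] > 0)
        members_t = n_a + np.flatnonzero(Yt[:, l] > 0)
        D_total = D_total + mmd_indicator(
            n_a, n_t, members_a=members_a, members_t=members_t, N=N
        )
    Lam = X @ D_total @ X.T
    return 0.5 * (Lam + Lam.T)


def class_indicators(
    n_a: int, n_t: int, Y_src: np.ndarray, Y_tgt: np.ndarray
) -> List[np.ndarray]:
    """Per-class MMD indicator matrices (zero for empty classes)."""
    N = n_a + n_t
    out = []
    for l in range(Y_src.shape[1]):
        members_a = np.flatnonzero(np.asarray(Y_src)[:, l] > 0)
        members_t = n_a + np.flatnonzero(np.asarray(Y_tgt)[:, l] > 0)
        out.append(
            mmd_indicator(n_a, n_t, members_a=members_a,
                          members_t=members_t, N=N)
        )
    return out


def alignment_matrix(
    X_pair,
    Y_src: np.ndarray,
    Y_tgt: np.ndarray,
    k: int = 5,
    gamma="auto",
    graph_mode: str = "printed",
) -> AlignmentOperators:
    """Build every alignment operator of one source-target pair.

    Returns the graph Laplacian, the marginal and class-conditional MMD
    indicators, the aggregate ``Lambda`` and ``C = X L X^T + Lambda``.
    """
    X = _values(X_pair)
    n_a = np.asarray(Y_src).shape[0]
    n_t = np.asarray(Y_tgt).shape[0]
    c = np.asarray(Y_src).shape[1]
    labels = None
    if graph_mode == "supervised":
        lab_s = np.asarray(Y_src).argmax(axis=1)
        lab_t = np.asarray(Y_tgt).argmax(axis=1)
        labels = np.concatenate([lab_s, lab_t])
    W = graph_adjacency(X, labels=labels, k=k, gamma=gamma, n_classes=c)
    L = graph_laplacian(W)
    D = mmd_indicator(n_a, n_t)
    D_class = class_indicators(n_a, n_t, Y_src, Y_tgt)
    Lam = lambda_matrix(X, Y_src, Y_tgt)
    C = X @ L @ X.T + Lam
    C = 0.5 * (C + C.T)
    return AlignmentOperators(L=L, D=D, D_class=D_class, Lambda=Lam, C=C)
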