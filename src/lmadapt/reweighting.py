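"""l2,1-norm and trace-norm machinery: norms and IRLS reweighting matrices.

The optimizer replaces every l2,1 term by its standard quadratic majorizer

    ||B||_{2,1} <= trace(B^T Q_A B) + 1/2 ||A||_{2,1},
    Q_A = diag( 1 / (2 ||A_i,:||_2) ),

with equality at B = A, and the trace norm by

    ||P||_* <= trace(P^T U_A P) + 1/2 ||A||_*,
    U_A = 1/2 (A A^T)^{-1/2}.

Exact-zero rows are the goal of l2,1 sparsification, so the row norms are
guarded at ``eps_num`` and the inverse square root is ridged by ``eps_num I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh


@dataclass
class DiagonalWeights:
    """Diagonal of an IRLS weight matrix; all entries positive and finite."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, float)
        if np.any(~np.isfinite(e)) or np.any(e <= 0):
            raise ValueError("diagonal weights must be positive and finite")
        self.entries = e

    def matrix(self) -> np.ndarray:
        return np.diag(self.entries)

    def __len__(self) -> int:
        return self.entries.size


def l21_norm(A: np.ndarray) -> float:
    """Sum of row 2-norms."""
    A = np.asarray(A, float)
    return float(np.linalg.norm(A, axis=1).sum())


def l21_weight_matrix(A: np.ndarray, eps_num: float = 1e-8) -> DiagonalWeights:
    """IRLS weights 1 / (2 max(||A_i,:||_2, eps_num)).

    Satisfies 2 trace(A^T Q A) = ||A||_{2,1} exactly on unguarded rows.
    """
    row_norms = np.linalg.norm(np.asarray(A, float), axis=1)
    return DiagonalWeights(1.0 / (2.0 * np.maximum(row_norms, eps_num)))


def trace_norm(P: np.ndarray) -> float:
    """Sum of singular values (nuclear norm)."""
    return float(np.linalg.svd(np.asarray(P, float), compute_uv=False).sum())


def inv_sqrt_psd(M: np.ndarray, eps_num: float = 1e-8) -> np.ndarray:
    """Inverse square root of a symmetric PSD matrix, eigenvalue-floored."""
    M = 0.5 * (M + M.T)
    vals, vecs = eigh(M)
    vals = np.maximum(vals, eps_num)
    return (vecs * (vals ** -0.5)) @ vecs.T


def trace_norm_weight(P: np.ndarray, eps_num: float = 1e-8) -> np.ndarray:
    """Trace-norm reweighting matrix U = 1/2 (P P^T + eps_num I)^{-1/2}.

    Symmetric positive definite; ``trace(P^T 2U P)`` approaches ``||P||_*``
    as ``eps_num -> 0`` for full-rank ``P P^T``.
    """
    P = np.asarray(P, float)
    r = P.shape[0]
    return 0.5 * inv_sqrt_psd(P @ P.T + eps_num * np.eye(r), eps_num=eps_num)
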