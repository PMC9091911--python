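"""Domain data structures for latent multi-source adaptation (LMA).

Conventions
-----------
Feature matrices are stored ``d x n`` (features in rows, samples in columns),
the convention used throughout the optimizer. File readers and the estimator
surface accept samples-as-rows and transpose on the way in.

Label matrices are ``n x c`` 0/1 indicators with exactly one 1 per row. A
``{-1,+1}`` export view exists for interoperability but is never used inside
the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import List, Optional, Sequence, Tuple

import numpy as np


class DomainError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_finite_2d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DomainError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise DomainError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite entries")
    return arr


@dataclass
class FeatureMatrix:
    """Dense real feature matrix, ``d`` features by ``n`` samples.

    Parameters
    ----------
    values : array-like, shape (d, n)
        Feature values, features in rows.
    sample_ids : sequence of str, optional
        Identifiers for the ``n`` samples.
    """

    values: np.ndarray
    sample_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.values = _as_finite_2d(self.values, "FeatureMatrix.values")
        if self.sample_ids is not None:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != self.values.shape[1]:
                raise DomainError(
                    "sample_ids length does not match the number of samples"
                )

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelMatrix:
    """0/1 class-indicator matrix, ``n`` samples by ``c`` classes."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_finite_2d(self.values, "LabelMatrix.values")
        if arr.shape[1] < 2:
            raise DomainError("LabelMatrix needs at least 2 classes")
        if not np.array_equal(arr, arr.astype(bool).astype(float)):
            raise DomainError("LabelMatrix entries must be 0 or 1")
        if not np.all(arr.sum(axis=1) == 1):
            raise DomainError("each LabelMatrix row must contain exactly one 1")
        self.values = arr

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]

    def to_labels(self) -> np.ndarray:
        """Decode to 1-based integer labels."""
        return self.values.argmax(axis=1) + 1

    def signed_view(self) -> np.ndarray:
        """Export as a {-1,+1} matrix (never used in the objective)."""
        return 2.0 * self.values - 1.0


def encode_one_hot(labels: Sequence[int], c: int) -> LabelMatrix:
    """One-hot encode 1-based integer labels into an ``n x c`` indicator.

    Raises
    ------
    DomainError
        If any label falls outside ``{1, ..., c}``.
    """
    lab = np.asarray(labels)
    if lab.ndim != 1 or lab.size == 0:
        raise DomainError("labels must be a non-empty 1-d integer vector")
    if not np.issubdtype(lab.dtype, np.integer):
        as_int = lab.astype(int)
        if not np.array_equal(as_int, lab):
            raise DomainError("labels must be integers")
        lab = as_int
    if lab.min() < 1 or lab.max() > c:
        raise DomainError(f"labels must lie in 1..{c}, got range "
                          f"[{lab.min()}, {lab.max()}]")
    out = np.zeros((lab.size, c))
    out[np.arange(lab.size), lab - 1] = 1.0
    return LabelMatrix(out)


@dataclass
class ScaledLabels:
    """Column-scaled indicator matrix F = Y (Y^T Y)^{-1/2}.

    Each non-empty class column is the indicator column divided by the square
    root of the class size, so the c x c transpose-product is the identity on
    non-empty classes. Rows of unlabeled samples stay all-zero.
    """

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


def scaled_label_matrix(Y) -> ScaledLabels:
    """Build the scaled (pseudo) label matrix from a 0/1 indicator.

    Rows may be all-zero (unlabeled samples); they remain all-zero. Empty
    classes yield zero columns.
    """
    arr = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y, dtype=float)
    counts = arr.sum(axis=0)
    scale = np.zeros_like(counts)
    nonempty = counts > 0
    scale[nonempty] = 1.0 / np.sqrt(counts[nonempty])
    if not np.all(nonempty):
        import logging

        logging.getLogger(__name__).debug(
            "scaled_label_matrix: %d empty class column(s) left at zero",
            int((~nonempty).sum()),
        )
    return ScaledLabels(arr * scale)


@dataclass
class MultiSourceProblem:
    """S labeled source domains plus one unlabeled target domain.

    All feature matrices share the feature dimension ``d``. A source missing
    samples of some class sets ``degenerate_classes``.
    """

    sources: List[Tuple[FeatureMatrix, LabelMatrix]]
    target: FeatureMatrix
    c: int
    degenerate_classes: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.sources:
            raise DomainError("need at least one source domain")
        d = self.target.d
        for i, (X, Y) in enumerate(self.sources):
            if X.d != d:
                raise DomainError(
                    f"source {i} has feature dimension {X.d}, target has {d}"
                )
            if X.n != Y.n:
                raise DomainError(f"source {i}: feature/label sample mismatch")
            if Y.c != self.c:
                raise DomainError(f"source {i}: class count {Y.c} != {self.c}")
            if np.any(Y.values.sum(axis=0) == 0):
                self.degenerate_classes = True

    @property
    def S(self) -> int:
        return len(self.sources)

    @property
    def d(self) -> int:
        return self.target.d


@dataclass
class Hyperparams:
    """Tunable parameters of the LMA objective and optimizer.

    Attributes
    ----------
    alpha, beta, lambda_ : float
        Nonnegative weights of the source-complexity, target-regularization
        and trace-norm coupling terms.
    q1, q2 : float
        Simplex-weight exponents, strictly greater than 1 (q=2 prevents the
        trivial one-hot weight solution).
    r : int or None
        Latent subspace dimension; ``None`` resolves to ``min(d, max(c, 2))``
        at fit time. Must satisfy r <= d (linear) or r <= N (kernel).
    k : int
        Nearest-neighbor count of the locality graphs; must be < node count.
    delta : float
        Source/target prediction fusion weight in [0, 1].
    kernel : KernelSpec-like or str
        Kernel specification; "linear" keeps everything in feature space.
    mkl : list or None
        Optional list of kernel specs for the stacked multiple-kernel map.
    max_iter : int
        Outer iteration cap.
    eps_tol : float
        Window stopping tolerance on the relative objective range.
    window : int
        Window length of the stopping rule.
    eps_num : float
        Guard for IRLS row norms and inverse square roots.
    gamma : float or "auto"
        Heat-kernel width of the adjacency graphs; "auto" uses
        sqrt(mean sample norm) / c.
    graph_mode : {"printed", "supervised"}
        Label-agnostic weights as printed, or drop different-label edges.
    data_fit : {"source_only", "pair"}
        Whether the robust data-fit term uses only labeled source samples or
        the packed source-target pair with pseudo-labeled target rows.
    refresh_operators : bool
        Re-estimate pseudo-labels and alignment operators every outer
        iteration (breaks the monotone-decrease guarantee; default off).
    seed : int
        Seed of the latent-weight initialization.
    """

    alpha: float = 1.0
    beta: float = 10.0
    lambda_: float = 1.0
    q1: float = 2.0
    q2: float = 2.0
    r: Optional[int] = None
    k: int = 5
    delta: float = 0.5
    kernel: object = "linear"
    mkl: Optional[list] = None
    max_iter: int = 100
    eps_tol: float = 1e-5
    window: int = 6
    eps_num: float = 1e-8
    gamma: object = "auto"
    graph_mode: str = "printed"
    data_fit: str = "source_only"
    refresh_operators: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda_"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")
        if self.q1 <= 1 or self.q2 <= 1:
            raise DomainError("q1 and q2 must be > 1")
        if self.r is not None and self.r < 1:
            raise DomainError("r must be a positive integer")
        if not 0.0 <= self.delta <= 1.0:
            raise DomainError("delta must lie in [0, 1]")
        if self.max_iter < 1 or self.window < 1:
            raise DomainError("max_iter and window must be positive")
        if self.eps_tol <= 0 or self.eps_num <= 0:
            raise DomainError("eps_tol and eps_num must be positive")
        if self.graph_mode not in ("printed", "supervised"):
            raise DomainError("graph_mode must be 'printed' or 'supervised'")
        if self.data_fit not in ("source_only", "pair"):
            raise DomainError("data_fit must be 'source_only' or 'pair'")

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ModelState:
    """All learned quantities of a fitted LMA model.

    Per source ``a``: the orthonormal-row subspace ``Theta[a]`` (r x d, or
    r x N in kernel mode), latent weights ``P[a]`` (r x c), composite
    classifier ``T[a]`` (d x c / N x c) and target label estimate ``F_a[a]``
    (n_t x c). Shared: target classifier ``W_t``, fused label estimate ``F``,
    and the simplex weight vectors ``vartheta`` (regression quality) and
    ``eta`` (alignment quality).
    """

    Theta: List[np.ndarray]
    P: List[np.ndarray]
    T: List[np.ndarray]
    F_a: List[np.ndarray]
    W_t: np.ndarray
    F: np.ndarray
    vartheta: np.ndarray
    eta: np.ndarray
    mode: str = "linear"
    # training references needed to embed new samples in kernel mode
    train_pairs: Optional[List[np.ndarray]] = None
    train_target: Optional[np.ndarray] = None
    kernel_specs: Optional[list] = None

    @property
    def S(self) -> int:
        return len(self.Theta)

    def validate(self, tol: float = 1e-8) -> None:
        """Check the documented invariants (orthonormal rows, simplexes)."""
        for a, Th in enumerate(self.Theta):
            r = Th.shape[0]
            if not np.allclose(Th @ Th.T, np.eye(r), atol=tol):
                raise DomainError(f"Theta[{a}] rows are not orthonormal")
        for name, v in (("vartheta", self.vartheta), ("eta", self.eta)):
            if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-10:
                raise DomainError(f"{name} is not on the simplex")
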