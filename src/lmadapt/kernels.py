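"""Kernel functions, empirical kernel maps and the stacked multi-kernel map.

Four nonlinear kernels are supported, all functions of the pairwise distance
``t = ||x - z||`` with width ``sigma``:

====================  ==============================
rbf                   exp(-sigma * t^2)
inv_sq_dist           1 / (1 + sigma * t^2)
laplacian             exp(-sigma * t)
inv_dist              1 / (1 + sigma * t)
====================  ==============================

``sigma="auto"`` resolves to ``1/d``. The "linear" spec bypasses the Gram
construction entirely: the empirical map is the identity on the query data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .types import DomainError, FeatureMatrix

KERNEL_NAMES = ("linear", "rbf", "laplacian", "inv_dist", "inv_sq_dist")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel name plus width; ``sigma="auto"`` means 1/d."""

    name: str = "rbf"
    sigma: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise DomainError(f"unknown kernel {self.name!r}; "
                              f"choose from {KERNEL_NAMES}")
        if self.sigma != "auto" and not float(self.sigma) > 0:
            raise DomainError("sigma must be positive or 'auto'")

    def resolve_sigma(self, d: int) -> float:
        return 1.0 / d if self.sigma == "auto" else float(self.sigma)


def as_spec(spec) -> KernelSpec:
    if isinstance(spec, KernelSpec):
        return spec
    if isinstance(spec, str):
        return KernelSpec(name=spec)
    if isinstance(spec, dict):
        return KernelSpec(**spec)
    raise DomainError(f"cannot interpret kernel spec {spec!r}")


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def kernel_matrix(X, Z, spec) -> np.ndarray:
    """Kernel Gram block K(x_i, z_j), shape ``n_X x n_Z``.

    ``X`` and ``Z`` are d x n feature matrices sharing d. The linear kernel
    returns plain inner products X^T Z.
    """
    spec = as_spec(spec)
    Xv, Zv = _values(X), _values(Z)
    if Xv.shape[0] != Zv.shape[0]:
        raise DomainError(
            f"feature dimensions differ: {Xv.shape[0]} vs {Zv.shape[0]}"
        )
    if spec.name == "linear":
        return Xv.T @ Zv
    sigma = spec.resolve_sigma(Xv.shape[0])
    if spec.name == "rbf":
        d2 = cdist(Xv.T, Zv.T, "sqeuclidean")
        return np.exp(-sigma * d2)
    if spec.name == "inv_sq_dist":
        d2 = cdist(Xv.T, Zv.T, "sqeuclidean")
        return 1.0 / (1.0 + sigma * d2)
    dist = cdist(Xv.T, Zv.T, "euclidean")
    if spec.name == "laplacian":
        return np.exp(-sigma * dist)
    return 1.0 / (1.0 + sigma * dist)  # inv_dist


def empirical_kernel_map(X_train, X_query, spec) -> np.ndarray:
    """Empirical kernel map of query points against the training set.

    Column j of the output is (K(x_1, q_j), ..., K(x_N, q_j)) for the N
    training samples. With a linear spec the map is the identity and the
    query data is returned unchanged (the classifier then lives in feature
    space rather than in the span of the training samples).
    """
    spec = as_spec(spec)
    if spec.name == "linear":
        Xq = _values(X_query)
        Xt = _values(X_train)
        if Xq.shape[0] != Xt.shape[0]:
            raise DomainError(
                f"feature dimensions differ: {Xt.shape[0]} vs {Xq.shape[0]}"
            )
        return Xq.copy()
    return kernel_matrix(X_train, X_query, spec)


def mkl_stack(X_train, X_query, specs: Sequence) -> np.ndarray:
    """Vertically stacked empirical kernel maps, shape ``(m*N) x n_query``.

    Concatenates the maps of the ``m`` kernel specs in order, building the
    integrated multi-kernel space used by the MKL variant.
    """
    specs = list(specs)
    if not specs:
        raise DomainError("mkl_stack needs at least one kernel spec")
    blocks: List[np.ndarray] = [
        empirical_kernel_map(X_train, X_query, s) for s in specs
    ]
    return np.vstack(blocks)
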