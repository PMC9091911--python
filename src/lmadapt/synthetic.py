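"""Seeded generator of multi-source domain-adaptation problems.

Emulates the statistical structure the adaptation model assumes for
EEG-derived feature vectors (e.g. differential-entropy band powers): shared
class-conditional Gaussian structure across domains, with each domain (every
source and the target) perturbed by an affine shift — a random mean offset
plus per-feature scale jitter — and, optionally, a fraction of samples
replaced by heavy outlier noise to exercise the l2,1 robustness terms.

Class means sit on the vertices of a regular simplex so every pair of classes
is separated by ``class_sep`` within-class standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Set, Tuple

import numpy as np

from .types import (
    DomainError,
    FeatureMatrix,
    LabelMatrix,
    MultiSourceProblem,
    encode_one_hot,
)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic multi-source generator.

    Attributes
    ----------
    S : source domain count.
    c : class count.
    d : feature dimension (must be >= c for the simplex placement).
    n_per_class : samples per class per domain.
    class_sep : pairwise distance between class means, in units of the
        within-class standard deviation (1).
    domain_shift : norm of each domain's random mean offset.
    domain_scale_jitter : half-width of the per-feature multiplicative scale
        perturbation, drawn from U(1 - jitter, 1 + jitter).
    outlier_frac : fraction of samples replaced in every source domain.
    outlier_scale : outlier noise standard deviation as a multiple of the
        overall data standard deviation.
    seed : generator seed; the same seed reproduces the problem bit-exactly.
    """

    S: int = 3
    c: int = 3
    d: int = 10
    n_per_class: int = 40
    class_sep: float = 6.0
    domain_shift: float = 1.0
    domain_scale_jitter: float = 0.1
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.S, self.c, self.d, self.n_per_class) < 1:
            raise DomainError("all counts must be positive")
        if self.d < self.c:
            raise DomainError("simplex placement needs d >= c")
        if not 0.0 <= self.outlier_frac <= 1.0:
            raise DomainError("outlier_frac must lie in [0, 1]")
        if self.domain_scale_jitter < 0 or self.domain_scale_jitter >= 1:
            raise DomainError("domain_scale_jitter must lie in [0, 1)")


def easy_preset(seed: int = 0) -> SynthConfig:
    """Well-separated classes, mild domain shift, no outliers."""
    return SynthConfig(
        class_sep=6.0, domain_shift=1.0, domain_scale_jitter=0.1,
        outlier_frac=0.0, seed=seed,
    )


def hard_preset(seed: int = 0) -> SynthConfig:
    """Closer classes, strong domain shift, 5% outliers."""
    return SynthConfig(
        class_sep=3.0, domain_shift=3.0, domain_scale_jitter=0.3,
        outlier_frac=0.05, seed=seed,
    )


def _class_means(c: int, d: int, class_sep: float) -> np.ndarray:
    """Centered regular-simplex vertices with pairwise distance class_sep."""
    means = np.zeros((c, d))
    means[:c, :c] = np.eye(c) * (class_sep / np.sqrt(2.0))
    return means - means.mean(axis=0)


def _unit_sphere(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # pragma: no cover - measure-zero event
        v = rng.standard_normal(d)
        norm = np.linalg.norm(v)
    return v / norm


def _sample_domain(
    rng: np.random.Generator, cfg: SynthConfig, means: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One domain: class-blocked samples around affinely shifted means."""
    offset = cfg.domain_shift * _unit_sphere(rng, cfg.d)
    scales = rng.uniform(
        1.0 - cfg.domain_scale_jitter, 1.0 + cfg.domain_scale_jitter, cfg.d
    )
    cols, labels = [], []
    for l in range(cfg.c):
        z = rng.standard_normal((cfg.d, cfg.n_per_class))
        x = scales[:, None] * (means[l][:, None] + z) + offset[:, None]
        cols.append(x)
        labels.extend([l + 1] * cfg.n_per_class)
    return np.hstack(cols), np.asarray(labels)


def inject_outliers(
    X: FeatureMatrix, frac: float, scale: float, seed: int = 0
) -> Tuple[FeatureMatrix, Set[int]]:
    """Replace ``floor(frac * n)`` uniformly chosen samples by Gaussian noise.

    The noise standard deviation is ``scale`` times the overall standard
    deviation of the data. Returns the corrupted matrix and the replaced
    column indices.
    """
    if not 0.0 <= frac <= 1.0:
        raise DomainError("frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = X.values.copy()
    n = values.shape[1]
    n_out = int(np.floor(frac * n))
    idx = rng.choice(n, size=n_out, replace=False)
    sd = float(values.std())
    values[:, idx] = rng.standard_normal((values.shape[0], n_out)) * scale * sd
    return FeatureMatrix(values, sample_ids=X.sample_ids), set(int(i) for i in idx)


def generate_problem(
    config: SynthConfig,
) -> Tuple[MultiSourceProblem, np.ndarray]:
    """Generate S labeled sources plus one unlabeled target.

    Returns the problem and the target's true labels, which the generator
    never hands to the optimizer. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    means = _class_means(config.c, config.d, config.class_sep)
    sources = []
    for a in range(config.S):
        Xv, labels = _sample_domain(rng, config, means)
        X = FeatureMatrix(Xv)
        if config.outlier_frac > 0:
            X, _ = inject_outliers(
                X, config.outlier_frac, config.outlier_scale,
                seed=int(rng.integers(2**31 - 1)),
            )
        sources.append((X, encode_one_hot(labels, config.c)))
    Xt, target_labels = _sample_domain(rng, config, means)
    problem = MultiSourceProblem(
        sources=sources, target=FeatureMatrix(Xt), c=config.c
    )
    return problem, target_labels


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """The same study conditions under a different seed."""
    return replace(config, seed=seed)
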