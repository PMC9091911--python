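"""Scikit-learn-style estimator wrapping the multi-source adaptation optimizer.

At this surface the usual scikit-learn orientation applies: feature arrays
are ``(n_samples, n_features)``, transposed internally into the optimizer's
features-by-samples layout.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .optimizer import fit as _fit
from .predict_eval import accuracy, fuse_predict
from .types import (
    DomainError,
    FeatureMatrix,
    Hyperparams,
    MultiSourceProblem,
    encode_one_hot,
)


class LMAClassifier(BaseEstimator, ClassifierMixin):
    """Robust latent multi-source adaptation classifier.

    Learns per-source robust classifiers in coupled orthogonal latent
    subspaces (l2,1 losses, trace-norm coupling, MMD + graph-Laplacian
    alignment against the unlabeled target) plus a target-space classifier,
    and predicts by delta-weighted fusion of the two.

    Parameters mirror :class:`~lmadapt.types.Hyperparams`; see there for the
    full description.

    Attributes
    ----------
    state_ : ModelState
        All learned matrices and simplex weights.
    trace_ : OptimizerTrace
        Per-iteration objective values, weights and the stopping reason.
    classes_ : ndarray
        The 1-based class labels.
    n_features_in_ : int
        Feature dimension seen at fit time.

    Examples
    --------
    >>> from lmadapt.synthetic import easy_preset, generate_problem
    >>> problem, y_true = generate_problem(easy_preset(seed=0))
    >>> clf = LMAClassifier().fit(
    ...     [(X.values.T, Y.to_labels()) for X, Y in problem.sources],
    ...     problem.target.values.T,
    ... )
    >>> float(clf.score(problem.target.values.T, y_true)) > 0.5
    True
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 10.0,
        lambda_: float = 1.0,
        q1: float = 2.0,
        q2: float = 2.0,
        r: Optional[int] = None,
        k: int = 5,
        delta: float = 0.5,
        kernel="linear",
        mkl=None,
        max_iter: int = 100,
        eps_tol: float = 1e-5,
        window: int = 6,
        eps_num: float = 1e-8,
        gamma="auto",
        graph_mode: str = "printed",
        data_fit: str = "source_only",
        refresh_operators: bool = False,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.lambda_ = lambda_
        self.q1 = q1
        self.q2 = q2
        self.r = r
        self.k = k
        self.delta = delta
        self.kernel = kernel
        self.mkl = mkl
        self.max_iter = max_iter
        self.eps_tol = eps_tol
        self.window = window
        self.eps_num = eps_num
        self.gamma = gamma
        self.graph_mode = graph_mode
        self.data_fit = data_fit
        self.refresh_operators = refresh_operators
        self.random_state = random_state

    def _hyperparams(self) -> Hyperparams:
        return Hyperparams(
            alpha=self.alpha, beta=self.beta, lambda_=self.lambda_,
            q1=self.q1, q2=self.q2, r=self.r, k=self.k, delta=self.delta,
            kernel=self.kernel, mkl=self.mkl, max_iter=self.max_iter,
            eps_tol=self.eps_tol, window=self.window, eps_num=self.eps_num,
            gamma=self.gamma, graph_mode=self.graph_mode,
            data_fit=self.data_fit, refresh_operators=self.refresh_operators,
            seed=self.random_state,
        )

    def fit(
        self,
        sources: List[Tuple[np.ndarray, Sequence[int]]],
        X_target: np.ndarray,
    ) -> "LMAClassifier":
        """Fit on labeled sources and the unlabeled target.

        Parameters
        ----------
        sources : list of (X, y)
            Per-source feature arrays ``(n_a, d)`` with 1-based integer
            labels of length ``n_a``.
        X_target : ndarray of shape (n_t, d)
            Unlabeled target features.
        """
        if not sources:
            raise DomainError("need at least one labeled source domain")
        X_target = check_array(X_target)
        labels_all = np.concatenate(
            [np.asarray(y).ravel() for _, y in sources]
        )
        classes = np.unique(labels_all.astype(int))
        c = int(classes.max())
        pairs = []
        for X, y in sources:
            X = check_array(X)
            pairs.append(
                (FeatureMatrix(X.T), encode_one_hot(np.asarray(y, int), c))
            )
        problem = MultiSourceProblem(
            sources=pairs, target=FeatureMatrix(X_target.T), c=c
        )
        self.state_, self.trace_ = _fit(problem, self._hyperparams())
        self.classes_ = np.arange(1, c + 1)
        self.n_features_in_ = X_target.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Fused decision values for samples-as-rows ``X``, shape (n, c)."""
        check_is_fitted(self, "state_")
        X = check_array(X)
        return fuse_predict(self.state_, X.T, self.delta).scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fused 1-based class labels for samples-as-rows ``X``."""
        check_is_fitted(self, "state_")
        X = check_array(X)
        return fuse_predict(self.state_, X.T, self.delta).labels

    def score(self, X: np.ndarray, y: Sequence[int]) -> float:
        """Accuracy of the fused prediction against 1-based labels."""
        return accuracy(self.predict(X), np.asarray(y, int))
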