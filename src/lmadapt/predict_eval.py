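"""Prediction fusion, accuracy, chance level and the leave-one-subject-out harness.

The fitted model yields two score matrices on probe data: the
vartheta-weighted source ensemble ``f_s = sum_a vartheta_a X^T T_a`` and the
target classifier ``f_t = X^T W_t``. Final labels are the row-argmax of the
delta-weighted fusion ``delta f_s + (1 - delta) f_t``; ties break toward the
lowest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kernels import empirical_kernel_map, mkl_stack
from .types import (
    DomainError,
    FeatureMatrix,
    Hyperparams,
    LabelMatrix,
    ModelState,
)

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Fused decision values, hard labels and the retained components."""

    scores: np.ndarray          # n x c fused decision values
    labels: np.ndarray          # length-n 1-based integer labels
    per_component: Dict[str, np.ndarray]   # "source" and "target" scores


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def _map_against(state: ModelState, train_raw: np.ndarray, X: np.ndarray) -> np.ndarray:
    specs = state.kernel_specs
    if specs is not None and len(specs) > 1:
        return mkl_stack(train_raw, X, specs)
    return empirical_kernel_map(train_raw, X, specs[0])


def source_scores(state: ModelState, X_test) -> np.ndarray:
    """vartheta-weighted source ensemble scores, shape n x c."""
    X = _values(X_test)
    n = X.shape[1]
    c = state.T[0].shape[1]
    out = np.zeros((n, c))
    for a in range(state.S):
        if state.mode == "kernel":
            Xa = _map_against(state, state.train_pairs[a], X)
        else:
            Xa = X
        if Xa.shape[0] != state.T[a].shape[0]:
            raise DomainError(
                f"test dimension {Xa.shape[0]} does not match classifier "
                f"dimension {state.T[a].shape[0]}"
            )
        out += state.vartheta[a] * (Xa.T @ state.T[a])
    return out


def target_scores(state: ModelState, X_test) -> np.ndarray:
    """Target-classifier scores X^T W_t, shape n x c."""
    X = _values(X_test)
    if state.mode == "kernel":
        X = _map_against(state, state.train_target, X)
    if X.shape[0] != state.W_t.shape[0]:
        raise DomainError(
            f"test dimension {X.shape[0]} does not match target classifier "
            f"dimension {state.W_t.shape[0]}"
        )
    return X.T @ state.W_t


def fuse_predict(state: ModelState, X_test, delta: float = 0.5) -> PredictionResult:
    """delta-weighted fusion of source and target scores with argmax labels."""
    if not 0.0 <= delta <= 1.0:
        raise DomainError("delta must lie in [0, 1]")
    fs = source_scores(state, X_test)
    ft = target_scores(state, X_test)
    fused = delta * fs + (1.0 - delta) * ft
    labels = fused.argmax(axis=1) + 1   # argmax breaks ties toward low index
    return PredictionResult(
        scores=fused, labels=labels,
        per_component={"source": fs, "target": ft},
    )


def accuracy(pred_labels: Sequence[int], true_labels: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise DomainError("prediction/label length mismatch")
    return float(np.mean(pred == true))


def chance_level(
    n: int,
    c: int,
    reps: int = 200,
    seed: int = 0,
    method: str = "uniform",
) -> Tuple[float, float]:
    """Empirical chance level of random prediction, in percent.

    Over ``reps`` replicates of ``n`` balanced true labels, either draw
    uniformly random predictions (``method="uniform"``) or randomly permute
    the true labels (``method="permutation"``); both are 100/c % in
    expectation. Returns the mean accuracy and the upper bound of its 95%
    confidence interval (normal approximation over replicates).
    """
    if n < 1 or c < 1 or reps < 1:
        raise DomainError("n, c and reps must be at least 1")
    if method not in ("uniform", "permutation"):
        raise DomainError("method must be 'uniform' or 'permutation'")
    rng = np.random.default_rng(seed)
    true = np.arange(n) % c + 1
    accs = np.empty(reps)
    for i in range(reps):
        if method == "uniform":
            pred = rng.integers(1, c + 1, size=n)
        else:
            pred = rng.permutation(true)
        accs[i] = np.mean(pred == true)
    mean_pct = 100.0 * accs.mean()
    sem_pct = 100.0 * accs.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return float(mean_pct), float(mean_pct + 1.96 * sem_pct)


def loso_evaluate(
    subject_datasets: List[Tuple[FeatureMatrix, LabelMatrix]],
    hyper: Optional[Hyperparams] = None,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation over a list of labeled subjects.

    Each subject in turn becomes the unlabeled target (its labels held out
    for scoring only) while the remaining subjects form the sources. Fit
    failures are recorded per fold, not fatal to the sweep. The returned
    table has one row per fold plus a "mean" row over successful folds.
    """
    from .optimizer import fit  # local import to avoid a cycle
    from .types import MultiSourceProblem

    if len(subject_datasets) < 2:
        raise DomainError("leave-one-subject-out needs at least 2 subjects")
    hyper = hyper or Hyperparams()
    rows = []
    for i, (X_held, Y_held) in enumerate(subject_datasets):
        sources = [
            (X, Y) for j, (X, Y) in enumerate(subject_datasets) if j != i
        ]
        try:
            problem = MultiSourceProblem(
                sources=sources, target=X_held, c=Y_held.c
            )
            state, _ = fit(problem, hyper)
            pred = fuse_predict(state, X_held, hyper.delta)
            acc = accuracy(pred.labels, Y_held.to_labels())
            rows.append({"fold": i, "accuracy": acc, "error": ""})
        except Exception as exc:  # recorded, not fatal
            logger.warning("fold %d failed: %s", i, exc)
            rows.append({"fold": i, "accuracy": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    mean_acc = table["accuracy"].mean(skipna=True)
    table = pd.concat(
        [table, pd.DataFrame([
            {"fold": "mean", "accuracy": mean_acc, "error": ""}
        ])],
        ignore_index=True,
    )
    return table
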