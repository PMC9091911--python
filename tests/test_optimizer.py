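import copy

import numpy as np
import pytest

from lmadapt.optimizer import (
    FrozenWeights,
    NumericError,
    converged,
    fit,
    freeze_weights,
    init_state,
    make_workspace,
    numeric_gradient_norm,
    objective,
    surrogate_objective,
    top_r_eigvec_rows,
    update_eta,
    update_F,
    update_Fa,
    update_Pa,
    update_Ta,
    update_vartheta,
    update_Wt,
)
from lmadapt.predict_eval import fuse_predict
from lmadapt.reweighting import DiagonalWeights, l21_norm, trace_norm
from lmadapt.synthetic import SynthConfig, easy_preset, generate_problem
from lmadapt.types import (
    FeatureMatrix,
    Hyperparams,
    MultiSourceProblem,
    encode_one_hot,
)


def _fitted(problem, hyper, iters=3):
    """A generic (partially optimized) state plus its workspace."""
    state, _ = fit(problem, Hyperparams(**{**hyper.asdict(), "max_iter": iters}))
    ws = make_workspace(problem, hyper)
    return state, ws


# ---------------------------------------------------------------------------
# objective


def _brute_objective(state, ws, h):
    """Straightforward term-by-term evaluator, independent of objective()."""
    row_norm_sum = lambda A: sum(np.sqrt((A[i] ** 2).sum()) for i in range(A.shape[0]))
    val = 0.0
    for a in range(ws.S):
        Ta = state.T[a]
        val += state.vartheta[a] ** h.q1 * row_norm_sum(
            ws.fit_Y[a] - ws.fit_X[a].T @ Ta
        )
        val += h.alpha * row_norm_sum(Ta)
        val += h.alpha * ((Ta - state.Theta[a].T @ state.P[a]) ** 2).sum()
        val += state.eta[a] ** h.q2 * (
            row_norm_sum(state.F_a[a] - ws.Xt_pair[a].T @ Ta)
            + np.trace(state.Theta[a] @ ws.ops[a].C @ state.Theta[a].T)
            + ((state.F_a[a] - state.F) ** 2).sum()
        )
    val += ((ws.Xt.T @ state.W_t - state.F) ** 2).sum()
    val += h.beta * (
        row_norm_sum(state.W_t) + np.trace(state.F.T @ ws.L_t @ state.F)
    )
    P = np.hstack(state.P)
    val += h.lambda_ / 2 * np.linalg.svd(P, compute_uv=False).sum()
    return val


def test_objective_matches_brute_force_evaluator(small_problem):
    problem, _ = small_problem
    h = Hyperparams()
    state, ws = _fitted(problem, h)
    assert np.isclose(
        objective(state, ws, h), _brute_objective(state, ws, h), atol=1e-10
    )


def test_objective_zero_state_equals_label_l21_norm():
    """With everything zeroed, only the data-fit term ||Y||_{2,1} survives."""
    X = FeatureMatrix(np.array([[1.0, -1.0], [0.5, 2.0]]))
    Y = encode_one_hot([1, 2], 2)
    problem = MultiSourceProblem(sources=[(X, Y)], target=X, c=2)
    h = Hyperparams(k=1)
    ws = make_workspace(problem, h)
    state = init_state(ws, h)
    state.Theta = [np.zeros_like(state.Theta[0])]
    state.P = [np.zeros_like(state.P[0])]
    state.T = [np.zeros_like(state.T[0])]
    state.F_a = [np.zeros_like(state.F_a[0])]
    state.F = np.zeros_like(state.F)
    state.W_t = np.zeros_like(state.W_t)
    state.vartheta = np.array([1.0])
    state.eta = np.array([1.0])
    assert np.isclose(objective(state, ws, h), 2.0)


def test_objective_linear_in_lambda(small_problem):
    problem, _ = small_problem
    h1 = Hyperparams(lambda_=1.0)
    state, ws = _fitted(problem, h1)
    h2 = Hyperparams(lambda_=2.0)
    diff = objective(state, ws, h2) - objective(state, ws, h1)
    assert np.isclose(diff, 0.5 * trace_norm(np.hstack(state.P)), atol=1e-10)


def test_objective_raises_on_non_finite(small_problem):
    problem, _ = small_problem
    h = Hyperparams()
    state, ws = _fitted(problem, h)
    state.W_t = state.W_t * np.inf
    with pytest.raises(NumericError, match="target"):
        objective(state, ws, h)


# ---------------------------------------------------------------------------
# closed-form reductions


def test_Wt_reduces_to_F_for_identity_target():
    """X_t = I and beta = 0 turn the target update into W_t = F."""
    X = FeatureMatrix(np.eye(2))
    Y = encode_one_hot([1, 2], 2)
    problem = MultiSourceProblem(sources=[(X, Y)], target=X, c=2)
    h = Hyperparams(beta=0.0, k=1)
    ws = make_workspace(problem, h)
    state = init_state(ws, h)
    state.F = np.array([[0.3, -0.1], [0.2, 0.9]])
    weights = freeze_weights(state, ws, h, warm_start=True)
    assert np.allclose(update_Wt(state, ws, h, weights), state.F)


def test_Wt_shrinks_with_beta(small_problem):
    problem, _ = small_problem
    state, ws = _fitted(problem, Hyperparams())
    norms = []
    for beta in (0.1, 10.0, 1000.0):
        h = Hyperparams(beta=beta)
        w = freeze_weights(state, ws, h)
        norms.append(np.linalg.norm(update_Wt(state, ws, h, w)))
    assert norms[0] > norms[1] > norms[2]


def test_Fa_update_identity_weights(small_problem):
    problem, _ = small_problem
    h = Hyperparams()
    state, ws = _fitted(problem, h)
    w = freeze_weights(state, ws, h)
    w.Zt[0] = DiagonalWeights(np.ones(ws.n_t))
    expected = 0.5 * (state.F + ws.Xt_pair[0].T @ state.T[0])
    assert np.allclose(update_Fa(state, 0, ws, h, w), expected)


def test_Fa_update_zero_classifier(small_problem):
    problem, _ = small_problem
    h = Hyperparams()
    state, ws = _fitted(problem, h)
    state.T[0] = np.zeros_like(state.T[0])
    w = freeze_weights(state, ws, h)
    z = w.Zt[0].entries[:, None]
    assert np.allclose(update_Fa(state, 0, ws, h, w), state.F / (1 + z))


def test_identical_sources_get_identical_Fa(small_problem):
    problem, _ = small_problem
    src = problem.sources[0]
    p2 = MultiSourceProblem(sources=[src, src], target=problem.target, c=3)
    state, _ = fit(p2, Hyperparams(max_iter=4))
    assert np.allclose(state.F_a[0], state.F_a[1])


def test_Ta_reduces_to_least_squares():
    """alpha = 0 and unit data weights recover the plain LS source fit."""
    rng = np.random.default_rng(3)
    Xs = FeatureMatrix(rng.standard_normal((4, 20)))
    Ys = encode_one_hot(rng.integers(1, 4, 20), 3)
    Xt = FeatureMatrix(rng.standard_normal((4, 10)))
    problem = MultiSourceProblem(sources=[(Xs, Ys)], target=Xt, c=3)
    h = Hyperparams(alpha=0.0, k=2)
    ws = make_workspace(problem, h)
    state = init_state(ws, h)
    w = freeze_weights(state, ws, h, warm_start=True)
    w.Zt[0] = DiagonalWeights(np.full(10, 1e-30))  # silence consistency term
    T = update_Ta(state, 0, ws, h, w)
    X, Y = Xs.values, Ys.values
    expected = np.linalg.solve(X @ X.T, X @ Y)
    assert np.allclose(T, expected, atol=1e-6)


def test_Pa_vanishes_for_large_lambda(small_problem):
    problem, _ = small_problem
    state, ws = _fitted(problem, Hyperparams())
    w = freeze_weights(state, ws, Hyperparams())
    small = update_Pa(state, 0, ws, Hyperparams(lambda_=1e9), w)
    base = update_Pa(state, 0, ws, Hyperparams(lambda_=1.0), w)
    assert np.linalg.norm(small) < 1e-6 * max(np.linalg.norm(base), 1e-12)


def test_Pa_zero_without_coupling(small_problem):
    problem, _ = small_problem
    state, ws = _fitted(problem, Hyperparams())
    h = Hyperparams(alpha=0.0)
    w = freeze_weights(state, ws, h)
    assert np.allclose(update_Pa(state, 0, ws, h, w), 0.0)


# ---------------------------------------------------------------------------
# eigen step


def test_top_eigvec_rows_diagonal_case():
    R = np.diag([3.0, 1.0, 2.0])
    Th = top_r_eigvec_rows(R, 2)
    assert np.allclose(np.abs(Th), [[1, 0, 0], [0, 0, 1]])
    assert np.isclose(np.trace(Th @ R @ Th.T), 5.0)


def test_top_eigvec_rows_identity_tie_break():
    Th = top_r_eigvec_rows(np.eye(4), 2)
    assert np.allclose(Th @ Th.T, np.eye(2))
    assert np.isclose(np.trace(Th @ np.eye(4) @ Th.T), 2.0)
    # deterministic: repeated calls agree
    assert np.array_equal(Th, top_r_eigvec_rows(np.eye(4), 2))


def test_top_eigvec_rows_achieves_top_eigenvalue_sum(rng):
    M = rng.standard_normal((7, 7))
    R = 0.5 * (M + M.T)
    Th = top_r_eigvec_rows(R, 3)
    vals = np.linalg.eigvalsh(R)
    assert np.isclose(np.trace(Th @ R @ Th.T), vals[-3:].sum(), atol=1e-8)


def test_top_eigvec_rows_r_too_large_rejected():
    from lmadapt.types import DomainError

    with pytest.raises(DomainError):
        top_r_eigvec_rows(np.eye(2), 3)


# ---------------------------------------------------------------------------
# simplex weights


@pytest.mark.parametrize(
    "g, q, expected",
    [
        ([1.0, 1.0], 2.0, [0.5, 0.5]),
        ([1.0, 3.0], 2.0, [0.75, 0.25]),
    ],
)
def test_vartheta_examples(g, q, expected):
    assert np.allclose(update_vartheta(np.array(g), q), expected)


@pytest.mark.parametrize(
    "h, q, expected",
    [
        ([2.0, 2.0], 3.0, [0.5, 0.5]),
        ([1.0, 4.0], 2.0, [0.8, 0.2]),
    ],
)
def test_eta_examples(h, q, expected):
    assert np.allclose(update_eta(np.array(h), q), expected)


def test_simplex_weights_sum_to_one_and_order(rng):
    g = rng.uniform(0.1, 5.0, 4)
    w = update_vartheta(g, 2.0)
    assert np.isclose(w.sum(), 1.0)
    assert np.all(np.argsort(w) == np.argsort(-g))  # smaller loss, larger weight


# ---------------------------------------------------------------------------
# convergence rule


def test_converged_examples():
    assert converged([10.0] * 6, 6, 1e-5)
    assert not converged([10.0] * 5, 6, 1e-5)
    assert not converged([10.0] * 5 + [10.0002], 6, 1e-5)  # sigma ~ 2e-5


def test_converged_ignores_history_outside_window():
    objs = [100.0, 50.0] + [10.0] * 6
    assert converged(objs, 6, 1e-5)


# ---------------------------------------------------------------------------
# full fit behavior


def test_fit_objective_monotone_and_trace_consistent(small_problem):
    problem, _ = small_problem
    state, trace = fit(problem, Hyperparams())
    obj = np.array(trace.objective)
    assert len(obj) >= 1 and np.all(np.isfinite(obj))
    if len(obj) > 1:
        rel = np.diff(obj) / np.abs(obj[:-1])
        assert rel.max() <= 1e-6
    assert len(trace.vartheta_history) == len(obj)
    assert trace.stopped_by in ("window", "max_iter")
    state.validate()


def test_fit_recovers_separable_classes(small_problem):
    problem, y = small_problem
    state, _ = fit(problem, Hyperparams())
    pred = fuse_predict(state, problem.target, 0.5)
    assert np.mean(pred.labels == y) >= 0.8


def test_fit_deterministic_given_seed(small_problem):
    problem, _ = small_problem
    s1, t1 = fit(problem, Hyperparams(max_iter=5))
    s2, t2 = fit(problem, Hyperparams(max_iter=5))
    assert np.array_equal(t1.objective, t2.objective)
    assert np.array_equal(s1.W_t, s2.W_t)


def test_predictions_invariant_under_feature_scaling():
    """Doubling all features (with the graph width rescaled to keep the same
    adjacency) leaves the predicted target labels unchanged."""
    problem, _ = generate_problem(easy_preset(0))
    g0, s = 0.05, 2.0
    st1, _ = fit(problem, Hyperparams(gamma=g0))
    scaled = MultiSourceProblem(
        sources=[(FeatureMatrix(X.values * s), Y) for X, Y in problem.sources],
        target=FeatureMatrix(problem.target.values * s),
        c=problem.c,
    )
    st2, _ = fit(scaled, Hyperparams(gamma=g0 / s**2))
    lab1 = fuse_predict(st1, problem.target, 0.5).labels
    lab2 = fuse_predict(st2, scaled.target, 0.5).labels
    assert np.mean(lab1 == lab2) >= 0.99


def test_kernel_mode_runs_and_is_monotone():
    cfg = SynthConfig(S=2, c=2, d=4, n_per_class=8, class_sep=5.0,
                      domain_shift=0.5, seed=2)
    problem, y = generate_problem(cfg)
    h = Hyperparams(kernel={"name": "rbf", "sigma": "auto"}, r=3, max_iter=25)
    state, trace = fit(problem, h)
    assert state.mode == "kernel"
    obj = np.array(trace.objective)
    assert (np.diff(obj) / np.abs(obj[:-1])).max() <= 1e-6
    state.validate()


# ---------------------------------------------------------------------------
# gradient oracle sanity


def test_gradient_oracle_not_vacuous(small_problem):
    """At a generic non-updated state the surrogate gradient is large."""
    problem, _ = small_problem
    h = Hyperparams()
    state, ws = _fitted(problem, h)
    rng = np.random.default_rng(0)
    state.W_t = state.W_t + rng.standard_normal(state.W_t.shape)
    w = freeze_weights(state, ws, h)
    assert numeric_gradient_norm(state, "W_t", ws, h, w) >= 1e-2
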