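import numpy as np
import pytest

from lmadapt.synthetic import SynthConfig, generate_problem
from lmadapt.types import Hyperparams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_problem():
    """A small, quickly solvable 2-source problem."""
    cfg = SynthConfig(
        S=2, c=3, d=5, n_per_class=8, class_sep=5.0, domain_shift=0.5,
        domain_scale_jitter=0.1, seed=11,
    )
    return generate_problem(cfg)


@pytest.fixture
def quick_hyper():
    return Hyperparams(max_iter=5)


def random_orthonormal_rows(rng, r, d):
    """Random matrix with orthonormal rows (helper used across tests)."""
    q, _ = np.linalg.qr(rng.standard_normal((d, r)))
    return q.T
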