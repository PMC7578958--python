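import numpy as np
import pytest

from emodrive.hmm import HMMParams


def random_hmm(rng: np.random.Generator, n_states: int = 3, n_symbols: int = 27) -> HMMParams:
    """A random valid model for property tests."""
    return HMMParams(
        pi=rng.dirichlet(np.ones(n_states)),
        A=rng.dirichlet(np.ones(n_states), size=n_states),
        B=rng.dirichlet(np.ones(n_symbols), size=n_states),
    )


def well_separated_model() -> HMMParams:
    """A sticky 3-state chain with sharply state-specific emissions.

    Each state concentrates on its own block of 9 symbols, so labels and EM
    both identify the states cleanly; used as ground truth for recovery tests.
    """
    pi = np.array([0.25, 0.45, 0.30])
    A = np.array(
        [
            [0.70, 0.20, 0.10],
            [0.15, 0.70, 0.15],
            [0.10, 0.20, 0.70],
        ]
    )
    B = np.full((3, 27), 0.2 / 18)
    for j in range(3):
        B[j, j * 9 : (j + 1) * 9] = 0.8 / 9
    return HMMParams(pi=pi, A=A, B=B)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def separated():
    return well_separated_model()
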