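import numpy as np
import pytest
from scipy.stats import rankdata

from connrep.synthetic import generate_var_fixture


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-sum identity (independent of any learning library)."""
    labels = np.asarray(labels, dtype=bool)
    pos, neg = np.sum(labels), np.sum(~labels)
    if pos == 0 or neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = rankdata(scores)
    return (np.sum(ranks[labels]) - pos * (pos + 1) / 2) / (pos * neg)


@pytest.fixture(scope="session")
def bivariate_coupled_coeffs():
    """VAR(1) with x driving y (coefficient 0.4), self-terms 0.9 and 0.5.

    Coefficient rows are targets: y's equation gets 0.4 * x(t-1)."""
    return np.array([[[0.9, 0.0],
                      [0.4, 0.5]]])


@pytest.fixture(scope="session")
def four_node_chain_coeffs():
    """Stationary 4-node VAR(2) chain with one long-range feedback edge."""
    a = np.zeros((2, 4, 4))
    a[0] = [[0.5, 0.0, 0.0, 0.0],
            [0.3, 0.4, 0.0, 0.0],
            [0.0, 0.3, 0.5, 0.0],
            [0.0, 0.0, 0.3, 0.4]]
    a[1, 0, 3] = 0.2
    return a


@pytest.fixture(scope="session")
def coupled_fixture(bivariate_coupled_coeffs):
    return generate_var_fixture(bivariate_coupled_coeffs, 1200, rng_seed=42)
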