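import numpy as np
import pytest

import spatocc as sp
from spatocc.mcmc import MCMCConfig


@pytest.fixture
def grid3x3():
    return sp.build_grid((0.0, 0.0, 12.0, 12.0), 4.0)


@pytest.fixture
def grid5x5():
    return sp.build_grid((0.0, 0.0, 20.0, 20.0), 4.0)


@pytest.fixture
def grid10x10():
    return sp.build_grid((0.0, 0.0, 40.0, 40.0), 4.0)


@pytest.fixture
def fast_mcmc():
    """Small but usable chain budget for unit tests."""
    return MCMCConfig(n_iter=1200, burn_in=600, thin=2, n_chains=1, seed=0)


@pytest.fixture
def sim_dataset(grid10x10):
    """Moderate-signal occupancy dataset on a 100-cell grid."""
    data, truth = sp.simulate_occupancy_dataset(
        grid10x10,
        beta=[-0.3, 1.2, 0.8],
        gamma=[0.6, 0.25],
        V_rho=0.4,
        visits_per_cell=3,
        seed=42,
    )
    return data, truth


def brute_force_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Independent oracle: concordant-pair fraction with ties counting 1/2."""
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_overlap(px: np.ndarray, py: np.ndarray) -> tuple[float, float, float]:
    """Independent oracle for (D, H, I) computed term by term."""
    d = 1.0 - 0.5 * sum(abs(a - b) for a, b in zip(px, py))
    h = sum((a**0.5 - b**0.5) ** 2 for a, b in zip(px, py)) ** 0.5
    return d, h, 1.0 - h * h / 2.0
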