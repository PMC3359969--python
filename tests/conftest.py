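import numpy as np
import pytest

from confspread import ModelParams, SimConfig, simulate

#: experimentally matched condition of the 34-protomer ring
BEST_FIT = ModelParams(ea0=0.65, ea1=0.65, ej=4.15, c_rel=1.0, n_protomers=34)
#: the classic high-cooperativity condition (EA = 1 kT, EJ = 4 kT)
DUKE = ModelParams(ea0=1.0, ea1=1.0, ej=4.0, c_rel=1.0, n_protomers=34)


@pytest.fixture(scope="session")
def bestfit_traj():
    """300 s neutral-bias trajectory at the best-fit parameters (~400 intervals)."""
    return simulate(BEST_FIT, SimConfig(duration=300.0, seed=11))


@pytest.fixture(scope="session")
def duke_traj():
    """300 s neutral-bias trajectory at EA=1, EJ=4."""
    return simulate(DUKE, SimConfig(duration=300.0, seed=13))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def batch_se(x: np.ndarray, n_batches: int = 30) -> float:
    """Standard error of the mean of an autocorrelated series via batch means."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
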