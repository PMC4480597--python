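import numpy as np
import pytest

from tdrp import SyntheticScenario, assemble_rate_sets, generate_dataset


@pytest.fixture(scope="session")
def noiseless():
    """Zero-noise power-law dataset: every quantity is exactly recoverable."""
    scen = SyntheticScenario(s_noise_cv=0.0, calib_halfwidth_frac=0.0, n_s_draws=10, seed=11)
    data, truth = generate_dataset(scen)
    return data, truth


@pytest.fixture(scope="session")
def noiseless_points(noiseless):
    data, truth = noiseless
    (pts,) = assemble_rate_sets(data, 1, 123)
    return pts, truth


@pytest.fixture(scope="session")
def noisy_points():
    """One realistically noisy resampled set (5 % s-noise, 15 % calib width)."""
    scen = SyntheticScenario(seed=7)
    data, truth = generate_dataset(scen)
    (pts,) = assemble_rate_sets(data, 1, 19)
    return pts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
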