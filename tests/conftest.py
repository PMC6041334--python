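import numpy as np
import pytest

from qibc.simulate import SimulationParams, simulate_features


@pytest.fixture(scope="session")
def default_features():
    """Measured feature table of a mid-sized default population."""
    return simulate_features(SimulationParams(n_cells=6000, seed=5))


@pytest.fixture(scope="session")
def staged_default(default_features):
    from qibc import staging

    staged = staging.stage_cells(default_features)
    return staging.bin_s_phase(staged)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
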