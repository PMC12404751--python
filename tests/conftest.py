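from __future__ import annotations

import numpy as np
import pytest

from glymflux import UromtConfig, make_phantom, run_series, simulate_dce_series


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(shape=(24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def scenario_series(phantom):
    """Default noiseless 15-frame influx-clearance series with ground truth."""
    return simulate_dce_series(phantom, noise_sd=0.0, n_frames=15, seed=1)


@pytest.fixture(scope="session")
def solved_maps(scenario_series):
    """r-flux maps from inverting the default scenario at default settings."""
    series, _ = scenario_series
    return run_series(series, UromtConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
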