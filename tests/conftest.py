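import numpy as np
import pandas as pd
import pytest

from holopheno.design import ExperimentDesign, SimulationParams
from holopheno.simulate import simulate_experiment


@pytest.fixture(scope="session")
def small_design():
    """Ten-day experiment with the drought window scaled into it."""
    return ExperimentDesign(
        duration_das=10, ds_window_das=(4, 8), rehydration_das=8
    )


@pytest.fixture(scope="session")
def params():
    return SimulationParams()


@pytest.fixture(scope="session")
def sim(small_design, params):
    """One shared small synthetic experiment (env, plants, otu, yield)."""
    return simulate_experiment(small_design, params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_delta_frame(deltas, significant, start="2018-09-01"):
    """Hand-built per-bin contrast frame for area-summary tests."""
    n = len(deltas)
    return pd.DataFrame(
        {
            "bin_start": pd.date_range(start, periods=n, freq="30min"),
            "delta": deltas,
            "p_value": [0.01 if s else 0.5 for s in significant],
            "significant": list(significant),
            "n_a": 4,
            "n_b": 4,
        }
    )
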