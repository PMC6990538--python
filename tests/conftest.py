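import warnings

import numpy as np
import pytest

from apctrend import FitConfig, fit_apc
from apctrend import validation as V


@pytest.fixture(scope="session")
def small_design():
    return V.small_design()


@pytest.fixture(scope="session")
def small_truth():
    return V.small_truth()


@pytest.fixture(scope="session")
def small_table(small_design, small_truth):
    rng = np.random.default_rng(42)
    return V.simulate_cell_means(small_truth, small_design, n_per_cell=200, rng=rng)


@pytest.fixture(scope="session")
def fitted_draws(small_table, small_design):
    """One converged full-model fit shared across forecast/changepoint tests."""
    cfg = FitConfig(chains=3, iterations=800, seed=7, max_doublings=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_apc(small_table, small_design, cfg)
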