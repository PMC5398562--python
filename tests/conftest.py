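import numpy as np
import pytest

from replicyto.params import PopulationParams
from replicyto.population import params_for_ratio, sample_population, with_seed


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_params():
    """Well-separated population (trimmed R/non-R target 6, F = 0.44)."""
    return params_for_ratio(6.0)


@pytest.fixture(scope="session")
def small_population(separable_params):
    """100 nuclei on a non-overlapping grid, fixed seed."""
    from dataclasses import replace

    return sample_population(replace(separable_params, n_cells=100, seed=7))


@pytest.fixture()
def bimodal_signals():
    """The hand-computable trim fixture: 34 nuclei at 10.0, 66 at 1.0."""
    return np.concatenate([np.full(34, 10.0), np.full(66, 1.0)])
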