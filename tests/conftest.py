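import numpy as np
import pytest

import flockfit as ff


@pytest.fixture(scope="session")
def biweekly_schedule():
    return np.arange(0.0, 225.0, 14.0)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic flock (201 birds, 17 ages), shared across tests."""
    return ff.simulate_flock(ff.default_design(seed=11))


@pytest.fixture(scope="session")
def default_g1_fits(default_dataset):
    results, table = ff.fit_flock(default_dataset.trajectories, model="g1")
    return results, table
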