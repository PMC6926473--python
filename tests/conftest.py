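import numpy as np
import pytest
from hypothesis import settings

import oscbias as ob

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated experiment (4 subjects x 500 trials), filtered + labeled."""
    cfg = ob.ObserverConfig(n_subjects=4, n_trials=500, seed=7)
    d = ob.simulate_dataset(cfg)
    d = ob.filter_trials(d)
    return ob.label_history(d, depth=2)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default generator (14 x 2800), filtered + labeled; shared
    across the parameter-recovery style tests to amortize simulation cost."""
    cfg = ob.ObserverConfig(seed=1)
    d = ob.simulate_dataset(cfg)
    d = ob.filter_trials(d)
    return ob.label_history(d, depth=2)


@pytest.fixture()
def bin_centers():
    return 0.2 + 0.01 * (np.arange(100) + 0.5)
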