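import numpy as np
import pytest

import cheeseboard.benchmarks as bm
from cheeseboard.synthetic import SimConfig


@pytest.fixture(scope="session")
def day(tmp_path_factory):
    """One full simulated day at benchmark scale, analyzed end to end.

    Shared across modules: recovery scores, pipeline products, bundle and
    ground truth of a single run.
    """
    out = tmp_path_factory.mktemp("day")
    return bm.session_recovery(seed=1, out_dir=str(out))


@pytest.fixture(scope="session")
def tiny_config():
    """A minutes-scale configuration for determinism/round-trip tests."""
    return SimConfig(n_pyr=10, n_int=6, n_trials=4, trial_duration=20.0,
                     probe_duration=90.0, rest_duration=60.0,
                     intertrial_gap=3.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
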