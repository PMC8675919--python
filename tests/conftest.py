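import numpy as np
import pytest

from odorddm import preprocessing, task


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic mouse: enough sessions that every condition is
    populated, small enough for per-test fitting."""
    return task.TaskConfig(n_sessions=12, seed=3)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return task.generate_mouse_dataset(small_config, mouse_id="m1")


@pytest.fixture(scope="session")
def small_preprocessed(small_trials):
    kept, _ = preprocessing.filter_sessions(small_trials)
    return preprocessing.normalize_reaction_times(kept)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
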