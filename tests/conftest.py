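import numpy as np
import pandas as pd
import pytest

from sterolome import RunConfig
from sterolome import simulate as sim


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def reference():
    return sim.default_reference()


@pytest.fixture(scope="session")
def zero_threshold_config():
    """Config with the instrument detection threshold disabled, for
    algebraic round-trip checks where trace components must not be
    truncated."""
    return RunConfig(area_threshold=0.0)


@pytest.fixture(scope="session")
def small_truth():
    """Noise-free 8-taxon cohort for exact round-trip checks."""
    return sim.make_truth(n_tips=8, noise_cv=0.0, seed=3)


@pytest.fixture(scope="session")
def small_tables(small_truth, reference, config):
    signals, metadata = sim.gen_sample_tables(
        small_truth, reference, replicates=2, seed=5, config=config
    )
    return signals, metadata


@pytest.fixture(scope="session")
def calib_tree():
    """100-tip ultrametric tree shared by the signal-calibration tests."""
    return sim.gen_tree(100, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_profiles():
    """Six samples in two clean compositional clusters."""
    data = {
        "s1": [0.70, 0.20, 0.10, 0.00],
        "s2": [0.65, 0.25, 0.10, 0.00],
        "s3": [0.72, 0.18, 0.10, 0.00],
        "s4": [0.05, 0.10, 0.25, 0.60],
        "s5": [0.08, 0.07, 0.25, 0.60],
        "s6": [0.06, 0.09, 0.30, 0.55],
    }
    return pd.DataFrame(data, index=["a", "b", "c", "d"]).T
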