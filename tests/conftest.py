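import numpy as np
import pandas as pd
import pytest

from fatiguelab import SimConfig, build_feature_table, simulate_session

# The published worked example: 100-row test-set confusion matrix
# (rows = actual level, columns = predicted level).
WORKED_MATRIX = np.array([[40, 6, 0], [4, 25, 1], [0, 3, 21]])

# Published per-gender mean reaction times (s) for levels 1-3.
MALE_RT_MEANS = (1.21, 1.30, 1.40)
FEMALE_RT_MEANS = (1.24, 1.35, 1.46)


@pytest.fixture(scope="session")
def demo_session():
    """A full-length session at a reduced sampling rate (shared, read-only)."""
    return simulate_session(SimConfig(duration_min=240.0, eeg_fs=64.0, rng_seed=1))


@pytest.fixture(scope="session")
def demo_table(demo_session) -> pd.DataFrame:
    return build_feature_table(demo_session)
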