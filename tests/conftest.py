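import numpy as np
import pytest

from methmargin.io import CpGIndex
from methmargin.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (15 patients x 7 positions)."""
    return simulate_cohort(SimConfig(seed=424242))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    from methmargin.evaluate import run_block_pipeline

    return run_block_pipeline(default_cohort)


@pytest.fixture()
def small_index():
    return CpGIndex({"chr1": np.array([10, 30, 50, 70, 90, 110])})
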