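import numpy as np
import pandas as pd
import pytest

from prc2kit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    return sd.generate_cohort(
        sd.CohortConfig(n_samples=300, n_genes=60, seed=7))


@pytest.fixture(scope="session")
def target_dataset():
    return sd.generate_target_dataset(sd.TargetsConfig(seed=3))


@pytest.fixture(scope="session")
def singlecell_dataset():
    return sd.generate_singlecell_dataset(sd.SingleCellConfig(seed=4))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
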