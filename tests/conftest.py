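import numpy as np
import pytest

from ptdyn.preprocessing import filter_cells, log_standardize, quantile_normalize
from ptdyn.synthetic import default_modules, generate_dataset


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-panel dataset at the standard noise conditions."""
    return generate_dataset(100, default_modules(), noise_sd=0.5,
                            dropout_rate=0.2, seed=3)


@pytest.fixture(scope="session")
def standardized(noisy_dataset):
    """Preprocessed gene-level z-scores for the noisy dataset."""
    filtered, _ = filter_cells(noisy_dataset.matrix)
    return log_standardize(quantile_normalize(filtered))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free default-panel dataset (ground-truth geometry intact)."""
    return generate_dataset(80, default_modules(), noise_sd=0.0,
                            dropout_rate=0.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
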