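import warnings

import numpy as np
import pytest

import protimpute as pi


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pi.generate_dataset(
            n_genes=200, seed=42, median_length_codons=120
        )


@pytest.fixture(scope="session")
def reference_dataset():
    """Dataset at the reference noise setting with realistic per-condition
    training sizes (~300 detected proteins)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pi.generate_dataset(
            n_genes=900, seed=42, median_length_codons=120
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
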