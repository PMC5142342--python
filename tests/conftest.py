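import warnings

import numpy as np
import pytest

from binsim.synthdata import SynthConfig, structured_dataset


@pytest.fixture(scope="session")
def structured_ds():
    """The default class-structured dataset (200 × 101, 4 classes, seed 0)."""
    return structured_dataset(SynthConfig(), seed=0)


@pytest.fixture(scope="session")
def tiny_ds():
    """A small labeled dataset for fast end-to-end checks."""
    return structured_dataset(SynthConfig(n_formulas=30), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(autouse=True)
def _no_allzero_row_warnings():
    # synthetic matrices occasionally produce all-zero rows by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*all-zero.*")
        yield
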