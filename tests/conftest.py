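import numpy as np
import pytest

import poseload as pl


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-sequence seeded dataset shared by read-only tests."""
    cfg = pl.GenConfig(n_sequences=60, seed=7)
    sequences, truths, splits = pl.generate_dataset(cfg)
    return cfg, sequences, truths, splits


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
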