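import numpy as np
import pytest

import fkeerf as fk
from fkeerf.belief_core import binary_frame


@pytest.fixture(scope="session")
def frame():
    return binary_frame()


@pytest.fixture(scope="session")
def fixture_dataset():
    """The shipped synthetic benchmark: 100+100 21-mers, motif strength 0.85."""
    return fk.default_fixture(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 30+30 dataset with a fully penetrant motif (separable)."""
    motif = fk.MotifSpec(positions=(4, 14), trinucleotides=("GAC", "CGA"), strength=1.0)
    return fk.gen_sequences(30, 30, 21, motif, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
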