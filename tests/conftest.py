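import numpy as np
import pytest

from refuge_phage.synthetic import SynthParams, generate_channels


@pytest.fixture(scope="session")
def synth_default():
    """One default-condition synthetic dataset shared across tests.

    100 channels x 3 replicates keeps every per-test statistic
    well-resolved while staying fast; parameters are otherwise the
    generator defaults (the study conditions).
    """
    return generate_channels(SynthParams(n_channels=100, n_replicates=3, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
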