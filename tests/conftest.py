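import numpy as np
import pytest

from tcperm import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_group_shuffled(rng):
    """8 samples, two orthogonal duplicated-row groups, shuffled, noiseless."""
    signal = np.array([[1.0, 1.0, 0.0, 0.0]] * 4 + [[0.0, 0.0, 2.0, 2.0]] * 4)
    labels = np.array([0] * 4 + [1] * 4)
    perm = rng.permutation(8)
    return signal[perm], labels[perm], signal


def standard_dataset(seed: int, snr: float | None, n_irrelevant: int = 0):
    """The benchmark design: 100 samples, 4 orthogonal groups, 300 bins."""
    return generate(
        SyntheticConfig(seed=seed, target_snr=snr, n_irrelevant=n_irrelevant)
    )
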