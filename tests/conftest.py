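import numpy as np
import pytest

from adeeg import CouplingSpec, default_coupling, generate_coupled_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_recording():
    """4-channel, 1000-sample recording with the default coupling."""
    return generate_coupled_recording(
        default_coupling(4), n_samples=1000, fs=128.0, seed=42, state="calm"
    )


@pytest.fixture(scope="session")
def coupled_pair_spec():
    """Channels 0/1 almost locked, channels 2/3 independent."""
    k = np.eye(4)
    k[0, 1] = k[1, 0] = 0.99
    return CouplingSpec(kappa=k)
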