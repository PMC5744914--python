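import numpy as np
import pytest

from olivesim.fixtures import make_fixture
from olivesim.input_stage import InputEnsembleConfig, SpikeTrain, SpikeTrainSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ensemble(rng, n_ex=3, n_inh=2, n_spikes=10, duration_ms=10.0,
                    on_us_grid=True):
    """Small random spike-train set for oracle comparisons (times in s).

    With ``on_us_grid`` spike times are multiples of 1 us so that a dense
    1-us grid oracle sees exactly the same event times.
    """
    def train():
        t = np.sort(rng.random(rng.integers(0, n_spikes + 1)) * duration_ms)
        if on_us_grid:
            t = np.round(t, 3)  # ms -> 1 us resolution
        return SpikeTrain(np.unique(t) * 1e-3)

    return SpikeTrainSet(
        excitatory=[train() for _ in range(n_ex)],
        inhibitory=[train() for _ in range(n_inh)],
        config=InputEnsembleConfig(m_ex=n_ex, m_inh=n_inh, spont_rate=0.0),
    )


@pytest.fixture
def eight_coincident():
    return make_fixture("eight_coincident")
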