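"""Hand-placed deterministic spike patterns for unit testing the neuron
models.  Each fixture is a tiny :class:`SpikeTrainSet` built from explicit
spike times (seconds); no randomness is involved."""

from __future__ import annotations

import numpy as np

from .input_stage import InputEnsembleConfig, SpikeTrain, SpikeTrainSet

__all__ = ["make_fixture", "fixture_names"]

_MS = 1e-3


def _build(ex_times: list, inh_times: list) -> SpikeTrainSet:
    return SpikeTrainSet(
        excitatory=[SpikeTrain(np.asarray(t, dtype=float)) for t in ex_times],
        inhibitory=[SpikeTrain(np.asarray(t, dtype=float)) for t in inh_times],
        config=InputEnsembleConfig(m_ex=len(ex_times), m_inh=len(inh_times),
                                   spont_rate=0.0),
    )


_REGISTRY = {
    # 8 simultaneous excitatory spikes: exactly at the coincidence threshold
    "eight_coincident": lambda: _build([[1.0 * _MS]] * 8, []),
    # two suprathreshold clusters 1 ms apart (closer than T_ref = 1.6 ms)
    "cluster_pair_1ms": lambda: _build([[1.0 * _MS, 2.0 * _MS]] * 8, []),
    # threshold-count excitation preceded by one inhibitory spike
    "eight_with_inhibition": lambda: _build([[1.0 * _MS]] * 8, [[0.5 * _MS]]),
    # one excitatory and one simultaneous inhibitory spike
    "ex_plus_inh_simultaneous": lambda: _build([[1.0 * _MS]], [[1.0 * _MS]]),
    # Stein-threshold probes (exponential theta = 5.5)
    "six_coincident": lambda: _build([[1.0 * _MS]] * 6, []),
    "five_coincident": lambda: _build([[1.0 * _MS]] * 5, []),
    "single_ex": lambda: _build([[1.0 * _MS]], []),
    "single_inh": lambda: _build([], [[1.0 * _MS]]),
    "empty": lambda: _build([], []),
}


def fixture_names() -> list:
    return sorted(_REGISTRY)


def make_fixture(name: str) -> SpikeTrainSet:
    """Return a named deterministic spike-pattern fixture."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}") from None
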