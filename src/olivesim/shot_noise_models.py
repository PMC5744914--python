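"""Shot-noise LSO models: coincidence counting and Stein (exponential/alpha).

These models have no physical membrane.  Their internal state -- the
'virtual membrane potential' -- is a direct kernel-weighted count of input
spikes, in units of unitary excitatory inputs.  An output spike is emitted
when the state reaches the threshold; the state is then reset to and held
at zero for the refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .input_stage import SpikeTrain, SpikeTrainSet

__all__ = [
    "CoincidenceParams",
    "SteinParams",
    "VirtualPotentialTrace",
    "exp_kernel",
    "alpha_kernel",
    "run_coincidence_counting",
    "run_stein",
    "CoincidenceCountingModel",
    "SteinModel",
]

#: Global integration step, ms (shared with the conductance-based models).
DEFAULT_DT = 0.002


@dataclass(frozen=True)
class CoincidenceParams:
    """Coincidence counting model parameters (times in ms, amplitudes in
    input counts)."""

    t_ref: float = 1.6
    theta: int = 8
    w_ex: float = 0.8
    h: int = 2
    w_inh: float = 1.6

    def __post_init__(self) -> None:
        if int(self.theta) != self.theta or self.theta <= 0:
            raise ValueError("the coincidence threshold must be a positive integer")
        if self.w_ex <= 0 or self.w_inh <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class SteinParams:
    """Stein model parameters.  ``kernel_kind`` selects exponential or alpha
    synaptic kernels; the excitatory amplitude is fixed to 1."""

    kernel_kind: str = "exponential"
    t_ref: float = 1.6
    theta: float = 5.5
    tau_ex: float = 0.70
    h: float = 1.8
    tau_inh: float = 0.98

    def __post_init__(self) -> None:
        if self.kernel_kind not in ("exponential", "alpha"):
            raise ValueError("kernel_kind must be 'exponential' or 'alpha'")
        if self.tau_ex <= 0 or self.tau_inh <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def exponential(cls) -> "SteinParams":
        return cls()

    @classmethod
    def alpha(cls) -> "SteinParams":
        return cls(kernel_kind="alpha", theta=7.3, tau_ex=0.45, h=1.7, tau_inh=0.63)


@dataclass
class VirtualPotentialTrace:
    """Virtual membrane potential sampled on the integration grid.

    ``t`` is in seconds, ``v`` in input units; ``v`` is zero wherever the
    model is refractory."""

    t: np.ndarray
    v: np.ndarray


def exp_kernel(t, tau: float, amp: float = 1.0):
    """Causal exponential kernel ``amp * e^{-t/tau}`` for t >= 0, else 0."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, amp * np.exp(-np.maximum(t, 0.0) / tau), 0.0)
    return out if out.ndim else float(out)


def alpha_kernel(t, tau: float, amp: float = 1.0):
    """Causal alpha kernel ``amp * (t/tau) e^{1 - t/tau}``; peaks at ``amp``
    at ``t = tau``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    tt = np.maximum(t, 0.0)
    out = np.where(t >= 0, amp * (tt / tau) * np.exp(1.0 - tt / tau), 0.0)
    return out if out.ndim else float(out)


def _pooled_times_ms(trains) -> np.ndarray:
    if not trains:
        return np.empty(0)
    t = np.concatenate([tr.times for tr in trains]) * 1e3
    t.sort(kind="stable")
    return t


def run_coincidence_counting(
    inputs: SpikeTrainSet, params: CoincidenceParams = CoincidenceParams()
) -> SpikeTrain:
    """Event-driven coincidence counting.

    At each excitatory arrival time ``t`` the model evaluates the count
    ``C(t) = #ex in (t - W_ex, t] - H * #inh in (t - W_inh, t]`` (half-open
    windows; simultaneous spikes all count) and fires iff ``C >= theta`` and
    the refractory period since the last output has elapsed.  Evaluating at
    excitatory arrivals only is sufficient: between arrivals the excitatory
    count can only fall and the inhibitory count can only deepen or recover,
    but ``C`` can newly reach the (positive) threshold only when an
    excitatory spike enters the window.
    """
    ex = _pooled_times_ms(inputs.excitatory)
    inh = _pooled_times_ms(inputs.inhibitory)
    if ex.size == 0:
        return SpikeTrain(np.empty(0))
    # half-open window (t - W, t]: a spike exactly W in the past is out;
    # the 1e-9 ms nudge keeps the boundary decision stable under float
    # round-off (event times are never that close unless exactly tied)
    eps = 1e-9
    n_ex = np.searchsorted(ex, ex, side="right") - np.searchsorted(
        ex, ex - params.w_ex + eps, side="left"
    )
    n_inh = np.searchsorted(inh, ex, side="right") - np.searchsorted(
        inh, ex - params.w_inh + eps, side="left"
    )
    count = n_ex - params.h * n_inh
    cand = ex[count >= params.theta]
    out = []
    last = -np.inf
    for t in cand:
        if t - last >= params.t_ref - eps:
            out.append(t)
            last = t
    return SpikeTrain(np.asarray(out) * 1e-3)


def _spike_steps(trains, dt: float, n_steps: int) -> np.ndarray:
    """Convert pooled spike times (s) to sorted integer step indices."""
    t = _pooled_times_ms(trains)
    idx = np.rint(t / dt).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_steps)]
    idx.sort(kind="stable")
    return idx


def run_stein(
    inputs: SpikeTrainSet,
    params: SteinParams = SteinParams(),
    dt: float = DEFAULT_DT,
    duration_ms: Optional[float] = None,
    record_trace: bool = True,
    refractory_inputs: str = "persist",
) -> Tuple[SpikeTrain, Optional[VirtualPotentialTrace]]:
    """Run a Stein model on the integration grid.

    The virtual potential is the linear sum of unit-amplitude excitatory
    kernels minus ``H`` times inhibitory kernels, computed by exact
    per-step exponential recursions.  At an output spike all kernel state
    is cleared and the potential is clamped to zero for ``T_ref``.
    ``refractory_inputs`` decides whether kernels started by inputs that
    arrive during the refractory period persist afterwards (default) or are
    discarded.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if refractory_inputs not in ("persist", "discard"):
        raise ValueError("refractory_inputs must be 'persist' or 'discard'")
    if duration_ms is None:
        if inputs.duration is None:
            raise ValueError("duration_ms required for hand-placed inputs")
        duration_ms = inputs.duration * 1e3
    n_steps = int(round(duration_ms / dt))
    ex = _spike_steps(inputs.excitatory, dt, n_steps)
    inh = _spike_steps(inputs.inhibitory, dt, n_steps)
    spikes, v = _kernels.stein_loop(
        ex,
        inh,
        n_steps,
        dt,
        params.kernel_kind == "alpha",
        float(params.theta),
        params.tau_ex,
        float(params.h),
        params.tau_inh,
        int(round(params.t_ref / dt)),
        refractory_inputs == "persist",
        record_trace,
    )
    train = SpikeTrain(spikes * dt * 1e-3)
    trace = (
        VirtualPotentialTrace(t=np.arange(n_steps) * dt * 1e-3, v=v)
        if record_trace
        else None
    )
    return train, trace


# ---------------------------------------------------------------------------
# model classes (uniform interface for the tuning-curve protocols)
# ---------------------------------------------------------------------------

class CoincidenceCountingModel:
    name = "coincidence"
    has_membrane = False

    def __init__(self, params: CoincidenceParams = CoincidenceParams()):
        self.params = params

    def simulate(self, inputs: SpikeTrainSet) -> SpikeTrain:
        return run_coincidence_counting(inputs, self.params)


class SteinModel:
    has_membrane = False

    def __init__(self, params: SteinParams, dt: float = DEFAULT_DT,
                 refractory_inputs: str = "persist"):
        self.params = params
        self.dt = dt
        self.refractory_inputs = refractory_inputs
        self.name = "stein_exp" if params.kernel_kind == "exponential" else "stein_alpha"

    def simulate(self, inputs: SpikeTrainSet) -> SpikeTrain:
        train, _ = run_stein(
            inputs,
            self.params,
            dt=self.dt,
            record_trace=False,
            refractory_inputs=self.refractory_inputs,
        )
        return train
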