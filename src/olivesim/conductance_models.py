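"""Conductance-based LSO models: passive/active integrate-and-fire and the
original/adjusted Wang-Colburn (Hodgkin-Huxley-type) models.

All membranes are single-compartment and integrated by explicit forward
Euler at a default step of 2 us.  The canonical unit system is ms / mV /
nS / pA / pF, so ``nS * mV = pA`` and ``pF / nS = ms``; spike-associated
current amplitudes quoted in nA are converted at load time.  Synaptic
input uses common alpha-function conductances (peak ``A`` reached one time
constant after the presynaptic spike) driving currents
``I = g(t) (E_rev - V)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from . import _kernels
from .input_stage import SpikeTrain, SpikeTrainSet
from .shot_noise_models import DEFAULT_DT, _spike_steps

__all__ = [
    "SynapticParams",
    "PassiveIFParams",
    "ActiveIFParams",
    "WangColburnParams",
    "MembraneTrace",
    "IntegrationResult",
    "synaptic_drive",
    "klva_gate",
    "rothman_manis_gates",
    "PassiveIF",
    "ActiveIF",
    "WangColburn",
    "run_passive_if",
    "run_active_if",
    "run_wang_colburn",
]


@dataclass(frozen=True)
class SynapticParams:
    """Alpha-function synaptic conductances (nS, ms, mV)."""

    a_ex: float = 3.5
    a_inh: float = 12.0
    tau_ex: float = 0.16
    tau_inh: float = 0.32
    e_ex: float = 0.0
    e_inh: float = -75.0

    @classmethod
    def wang_colburn_original(cls) -> "SynapticParams":
        """The original Wang-Colburn study used E_inh = -70 mV."""
        return cls(e_inh=-70.0)


@dataclass(frozen=True)
class PassiveIFParams:
    """Leaky (RC) integrate-and-fire membrane (pF, nS, mV, ms)."""

    c: float = 24.0
    g_l: float = 26.4
    e_l: float = -60.0
    v_reset: float = -60.0
    v_theta: float = -45.3
    t_ref: float = 1.6


@dataclass(frozen=True)
class ActiveIFParams:
    """IF membrane with a low-voltage-activated potassium (KLVA) conductance
    and a spike-associated current ``24 e^{-t/0.15} - 12 e^{-t/0.30}`` nA."""

    c: float = 24.0
    g_l: float = 14.4
    g_kl: float = 21.6
    e_l: float = -56.0
    e_k: float = -75.0
    v_theta: float = -45.8
    t_ref: float = 1.6


@dataclass(frozen=True)
class WangColburnParams:
    """HH-type membrane with leak, KLVA, KHVA and fast Na conductances.

    Gating kinetics follow Rothman-Manis type-II VCN kinetics, with all
    rates multiplied by the temperature factor ``phi = Q10^{(T-22)/10}``
    and voltages shifted by ``v_shift``.
    """

    c: float = 31.4
    g_l: float = 31.4
    g_kl: float = 85.0
    g_kh: float = 1200.0
    g_na: float = 8000.0
    e_l: float = -65.0
    e_k: float = -70.0
    e_na: float = 50.0
    q10: float = 3.0
    t_body: float = 37.0
    v_shift: float = 0.0

    @property
    def phi(self) -> float:
        return self.q10 ** ((self.t_body - 22.0) / 10.0)

    @classmethod
    def original(cls) -> "WangColburnParams":
        return cls()

    @classmethod
    def adjusted(cls) -> "WangColburnParams":
        return cls(
            c=24.0,
            g_l=24.0,
            g_kl=15.0,
            g_kh=440.0,
            g_na=4400.0,
            e_l=-60.0,
            e_k=-75.0,
            v_shift=5.0,
        )


@dataclass
class MembraneTrace:
    """Membrane potential time series: ``t`` in s, ``v`` in mV."""

    t: np.ndarray
    v: np.ndarray


@dataclass
class IntegrationResult:
    spikes: SpikeTrain
    trace: Optional[MembraneTrace]
    state: np.ndarray
    gate_range: Optional[Tuple[float, float]] = None


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

def klva_gate(v):
    """Active-IF KLVA gate: steady state and time constant (ms) at ``v``.

    ``alpha = 0.5 e^{(v+50)/16}``, ``beta = 0.5 e^{-(v+50)/16}``;
    ``d_inf = alpha/(alpha+beta)``, ``tau_d = 1/(alpha+beta)``.
    """
    v = np.asarray(v, dtype=float)
    a = 0.5 * np.exp((v + 50.0) / 16.0)
    b = 0.5 * np.exp(-(v + 50.0) / 16.0)
    d_inf = a / (a + b)
    tau_d = 1.0 / (a + b)
    if d_inf.ndim:
        return d_inf, tau_d
    return float(d_inf), float(tau_d)


def rothman_manis_gates(v, v_shift: float = 0.0, phi: float = 1.0) -> dict:
    """Steady states and effective time constants (``tau_x / phi``, ms) of
    the six Wang-Colburn gating variables at membrane potential ``v``."""
    vs = np.asarray(v, dtype=float) - v_shift
    exp = np.exp
    out = {
        "w": (
            (1.0 / (1.0 + exp(-(vs + 48.0) / 6.0))) ** 0.25,
            1.5 + 100.0 / (6.0 * exp((vs + 60.0) / 6.0) + 16.0 * exp(-(vs + 60.0) / 45.0)),
        ),
        "z": (
            0.5 + 0.5 / (1.0 + exp((vs + 71.0) / 10.0)),
            50.0 + 1000.0 / (exp((vs + 60.0) / 20.0) + exp(-(vs + 60.0) / 8.0)),
        ),
        "n": (
            (1.0 / (1.0 + exp(-(vs + 15.0) / 5.0))) ** 0.5,
            0.7 + 100.0 / (11.0 * exp((vs + 60.0) / 24.0) + 21.0 * exp(-(vs + 60.0) / 23.0)),
        ),
        "p": (
            1.0 / (1.0 + exp(-(vs + 23.0) / 6.0)),
            5.0 + 100.0 / (4.0 * exp((vs + 60.0) / 32.0) + 5.0 * exp(-(vs + 60.0) / 22.0)),
        ),
        "m": (
            1.0 / (1.0 + exp(-(vs + 38.0) / 7.0)),
            0.04 + 10.0 / (5.0 * exp((vs + 60.0) / 18.0) + 36.0 * exp(-(vs + 60.0) / 25.0)),
        ),
        "h": (
            1.0 / (1.0 + exp((vs + 65.0) / 6.0)),
            0.6 + 100.0 / (7.0 * exp((vs + 60.0) / 11.0) + 10.0 * exp(-(vs + 60.0) / 25.0)),
        ),
    }
    return {k: (inf, tau / phi) for k, (inf, tau) in out.items()}


def synaptic_drive(
    inputs: SpikeTrainSet,
    params: SynapticParams = SynapticParams(),
    dt: float = DEFAULT_DT,
    duration_ms: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Total excitatory and inhibitory conductances (nS) on the grid."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration_ms is None:
        if inputs.duration is None:
            raise ValueError("duration_ms required for hand-placed inputs")
        duration_ms = inputs.duration * 1e3
    n_steps = int(round(duration_ms / dt))
    ex = _spike_steps(inputs.excitatory, dt, n_steps)
    inh = _spike_steps(inputs.inhibitory, dt, n_steps)
    g_ex = _kernels.alpha_conductance(ex, n_steps, dt, params.tau_ex, params.a_ex)
    g_inh = _kernels.alpha_conductance(inh, n_steps, dt, params.tau_inh, params.a_inh)
    return g_ex, g_inh


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

_EMPTY_STEPS = np.empty(0, np.int64)
_EMPTY_F64 = np.empty(0)


class _ConductanceModel:
    """Shared integration plumbing for the membrane models."""

    has_membrane = True
    name = ""

    def __init__(self, params, syn: SynapticParams, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > DEFAULT_DT * (1 + 1e-9):
            import warnings

            warnings.warn(f"dt = {dt} ms exceeds the 2 us default; accuracy may degrade")
        self.params = params
        self.syn = syn
        self.dt = dt
        self._rest_cache = None

    # subclasses: number of state variables and steady-state init
    def initial_state(self, v0: float) -> np.ndarray:
        raise NotImplementedError

    def _run(self, ex, inh, n_steps, i_const, i_arr, spikes_enabled, state0,
             record, na_enabled):
        raise NotImplementedError

    def integrate(
        self,
        inputs: Optional[SpikeTrainSet] = None,
        duration_ms: Optional[float] = None,
        i_ext: Union[float, np.ndarray] = 0.0,
        spikes_enabled: bool = True,
        state0: Optional[np.ndarray] = None,
        v0: Optional[float] = None,
        record: bool = True,
        na_enabled: bool = True,
    ) -> IntegrationResult:
        """Forward-Euler integration.

        ``i_ext`` may be a constant (pA) or an array sampled per step.
        ``state0`` continues from a previous run's final state; otherwise
        the membrane starts at ``v0`` (default: leak reversal) with gates
        at their steady state for ``v0``.  ``na_enabled`` is honored by the
        Wang-Colburn models only.
        """
        if duration_ms is None:
            if inputs is None or inputs.duration is None:
                raise ValueError("duration_ms or timed inputs required")
            duration_ms = inputs.duration * 1e3
        n_steps = int(round(duration_ms / self.dt))
        if inputs is not None:
            ex = _spike_steps(inputs.excitatory, self.dt, n_steps)
            inh = _spike_steps(inputs.inhibitory, self.dt, n_steps)
        else:
            ex = inh = _EMPTY_STEPS
        if np.ndim(i_ext) == 0:
            i_const, i_arr = float(i_ext), _EMPTY_F64
        else:
            i_arr = np.ascontiguousarray(i_ext, dtype=float)
            if i_arr.size != n_steps:
                raise ValueError("i_ext array must have one sample per step")
            i_const = 0.0
        if state0 is None:
            state0 = self.initial_state(self.params.e_l if v0 is None else v0)
        state0 = np.asarray(state0, dtype=float)
        spikes, v_tr, state, gates = self._run(
            ex, inh, n_steps, i_const, i_arr, spikes_enabled, state0, record,
            na_enabled,
        )
        trace = (
            MembraneTrace(t=np.arange(n_steps) * self.dt * 1e-3, v=v_tr)
            if record
            else None
        )
        return IntegrationResult(
            spikes=SpikeTrain(spikes * self.dt * 1e-3),
            trace=trace,
            state=state,
            gate_range=gates,
        )

    def rest_state(self, settle_ms: float = 200.0) -> np.ndarray:
        """Membrane state after settling with no input (gates initialized at
        their steady state for the leak reversal).  Cached per instance."""
        key = settle_ms
        if self._rest_cache is None or self._rest_cache[0] != key:
            res = self.integrate(
                duration_ms=settle_ms, spikes_enabled=False, record=False
            )
            self._rest_cache = (key, res.state)
        return self._rest_cache[1].copy()

    def resting_potential(self, settle_ms: float = 1000.0) -> float:
        return float(self.rest_state(settle_ms)[0])

    def simulate(self, inputs: SpikeTrainSet) -> SpikeTrain:
        """Run on a stimulus ensemble after a 200 ms no-input settle."""
        res = self.integrate(
            inputs=inputs, record=False, state0=self.rest_state(200.0)
        )
        return res.spikes


class PassiveIF(_ConductanceModel):
    name = "if_passive"

    def __init__(
        self,
        params: PassiveIFParams = PassiveIFParams(),
        syn: SynapticParams = SynapticParams(),
        dt: float = DEFAULT_DT,
    ):
        super().__init__(params, syn, dt)

    def initial_state(self, v0: float) -> np.ndarray:
        return np.array([v0])

    def _run(self, ex, inh, n_steps, i_const, i_arr, spikes_enabled, state0,
             record, na_enabled):
        p, s = self.params, self.syn
        spikes, v_tr, state = _kernels.passive_if_loop(
            ex, inh, n_steps, self.dt,
            p.c, p.g_l, p.e_l, p.v_reset, p.v_theta, int(round(p.t_ref / self.dt)),
            s.a_ex, s.tau_ex, s.e_ex, s.a_inh, s.tau_inh, s.e_inh,
            i_const, i_arr, spikes_enabled, state0[0], record,
        )
        return spikes, v_tr, state, None


class ActiveIF(_ConductanceModel):
    name = "if_active"

    def __init__(
        self,
        params: ActiveIFParams = ActiveIFParams(),
        syn: SynapticParams = SynapticParams(),
        dt: float = DEFAULT_DT,
    ):
        super().__init__(params, syn, dt)

    def initial_state(self, v0: float) -> np.ndarray:
        d_inf, _ = klva_gate(v0)
        return np.array([v0, d_inf])

    def _run(self, ex, inh, n_steps, i_const, i_arr, spikes_enabled, state0,
             record, na_enabled):
        p, s = self.params, self.syn
        spikes, v_tr, state, dmin, dmax = _kernels.active_if_loop(
            ex, inh, n_steps, self.dt,
            p.c, p.g_l, p.g_kl, p.e_l, p.e_k, p.v_theta,
            int(round(p.t_ref / self.dt)),
            s.a_ex, s.tau_ex, s.e_ex, s.a_inh, s.tau_inh, s.e_inh,
            i_const, i_arr, spikes_enabled, state0[0], state0[1], record,
        )
        return spikes, v_tr, state, (dmin, dmax)


class WangColburn(_ConductanceModel):
    def __init__(
        self,
        params: WangColburnParams,
        syn: Optional[SynapticParams] = None,
        dt: float = DEFAULT_DT,
        name: str = "wc",
    ):
        if syn is None:
            syn = SynapticParams()
        super().__init__(params, syn, dt)
        self.name = name

    @classmethod
    def original(cls, dt: float = DEFAULT_DT) -> "WangColburn":
        return cls(
            WangColburnParams.original(),
            SynapticParams.wang_colburn_original(),
            dt=dt,
            name="wc_original",
        )

    @classmethod
    def adjusted(cls, dt: float = DEFAULT_DT) -> "WangColburn":
        return cls(WangColburnParams.adjusted(), SynapticParams(), dt=dt,
                   name="wc_adjusted")

    def initial_state(self, v0: float) -> np.ndarray:
        g = rothman_manis_gates(v0, self.params.v_shift, self.params.phi)
        return np.array([v0] + [g[x][0] for x in "wznpmh"])

    def _run(self, ex, inh, n_steps, i_const, i_arr, spikes_enabled, state0,
             record, na_enabled):
        p, s = self.params, self.syn
        spikes, v_tr, state, gmin, gmax = _kernels.wc_loop(
            ex, inh, n_steps, self.dt,
            p.c, p.g_l, p.g_kl, p.g_kh, p.g_na if na_enabled else 0.0,
            p.e_l, p.e_k, p.e_na, p.v_shift, p.phi,
            s.a_ex, s.tau_ex, s.e_ex, s.a_inh, s.tau_inh, s.e_inh,
            i_const, i_arr, spikes_enabled, state0, record,
        )
        return spikes, v_tr, state, (gmin, gmax)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def run_passive_if(inputs, params=None, syn=None, dt=DEFAULT_DT, i_ext=0.0,
                   **kw):
    model = PassiveIF(params or PassiveIFParams(), syn or SynapticParams(), dt)
    res = model.integrate(inputs=inputs, i_ext=i_ext, **kw)
    return res.trace, res.spikes


def run_active_if(inputs, params=None, syn=None, dt=DEFAULT_DT, i_ext=0.0,
                  **kw):
    model = ActiveIF(params or ActiveIFParams(), syn or SynapticParams(), dt)
    res = model.integrate(inputs=inputs, i_ext=i_ext, **kw)
    return res.trace, res.spikes


def run_wang_colburn(inputs, params=None, syn=None, dt=DEFAULT_DT, i_ext=0.0,
                     **kw):
    model = WangColburn(params or WangColburnParams.original(),
                        syn or SynapticParams.wang_colburn_original(), dt)
    res = model.integrate(inputs=inputs, i_ext=i_ext, **kw)
    return res.trace, res.spikes
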