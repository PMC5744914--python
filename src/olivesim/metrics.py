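"""Output measures and membrane-characterization protocols.

Tuning-curve measures (shared by all seven models):

* rate-MTF -- mean output rate vs. modulation frequency of a monaural AM
  tone, with the synch-MTF (modulation gain ``20 log10(2 R)``, ``R`` the
  output vector strength) as companion;
* binaural phase tuning -- rate vs. envelope phase difference of binaural
  AM tones (positive difference = inhibition leads);
* binaural level (ILD) tuning -- rate vs. contralateral level at a fixed
  ipsilateral level (ILD = contra - ipsi).

Each curve is summarized by peak, trough and depth (peak - trough) and the
nine resulting numbers are scored against targeted/accepted spike-rate
ranges.  Membrane protocols (conductance-based models only): impedance,
I-V curve with DC input resistance, step-current phasic/tonic
classification, and unitary PSP calibration on the spikeless RC membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .conductance_models import (
    MembraneTrace,
    PassiveIF,
    PassiveIFParams,
    SynapticParams,
    _ConductanceModel,
)
from .input_stage import (
    InputEnsembleConfig,
    SpikeTrain,
    SpikeTrainSet,
    StimulusSpec,
    build_input_set,
)

__all__ = [
    "vector_strength",
    "modulation_gain",
    "TuningCurve",
    "TuningStats",
    "Interval",
    "RangeSpec",
    "TABLE1_RANGES",
    "rate_mtf",
    "phase_tuning",
    "ild_tuning",
    "tuning_stats",
    "score_against_ranges",
    "calibration_summary",
    "clamp_bias",
    "dc_input_resistance",
    "iv_curve",
    "impedance_profile",
    "classify_step_response",
    "unitary_psp",
    "psp_metrics",
    "DEFAULT_FM_GRID",
    "DEFAULT_PHASE_GRID",
    "DEFAULT_CONTRA_GRID",
]

# protocol grids (the study protocol spans; step sizes are our choice)
DEFAULT_FM_GRID = np.arange(50.0, 1201.0, 50.0)
DEFAULT_PHASE_GRID = np.arange(16) / 16.0 - 0.5
DEFAULT_CONTRA_GRID = np.arange(-10.0, 51.0, 5.0)

_PROTO_RATE, _PROTO_PHASE, _PROTO_ILD = 1, 2, 3


# ---------------------------------------------------------------------------
# spike-train measures
# ---------------------------------------------------------------------------

def vector_strength(spikes: SpikeTrain, f: float) -> float:
    """Goldberg-Brown vector strength of spike times at frequency ``f``:
    ``R = |sum_j exp(i 2 pi f t_j)| / N``."""
    if f <= 0:
        raise ValueError("f must be positive")
    t = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    if t.size == 0:
        raise ValueError("vector strength is undefined for an empty train")
    ph = 2.0 * np.pi * f * t
    return float(np.hypot(np.cos(ph).mean(), np.sin(ph).mean()))


def modulation_gain(r: float) -> float:
    """Modulation gain ``20 log10(2 R)`` in dB."""
    if r < 0:
        raise ValueError("vector strength must be non-negative")
    if r == 0:
        warnings.warn("zero vector strength: modulation gain is -inf")
        return -np.inf
    return 20.0 * np.log10(2.0 * r)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Rates (spikes/s) sampled over a stimulus variable ``x``."""

    x: np.ndarray
    rate: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.rate < -1e-12):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TuningStats:
    peak: float
    trough: float

    @property
    def depth(self) -> float:
        return self.peak - self.trough


def tuning_stats(curve: TuningCurve) -> TuningStats:
    """Peak and trough are grid extrema (no interpolation)."""
    return TuningStats(peak=float(curve.rate.max()), trough=float(curve.rate.min()))


def _run_point(model, stimulus, config, seed, proto, idx):
    inputs = build_input_set(stimulus, config, seed, spawn_prefix=(proto, idx))
    spikes = model.simulate(inputs)
    return spikes, spikes.rate(stimulus.duration)


def rate_mtf(
    model,
    f_grid: Sequence[float] = DEFAULT_FM_GRID,
    duration: float = 40.0,
    seed: int = 0,
    config: InputEnsembleConfig = InputEnsembleConfig(),
) -> Tuple[TuningCurve, TuningCurve]:
    """Monaural AM tuning: returns (rate-MTF, synch-MTF in dB)."""
    rates, gains = [], []
    for i, f_m in enumerate(f_grid):
        stim = StimulusSpec.am_monaural(f_m=float(f_m), duration=duration)
        spikes, rate = _run_point(model, stim, config, seed, _PROTO_RATE, i)
        rates.append(rate)
        gains.append(
            modulation_gain(vector_strength(spikes, f_m)) if len(spikes) else np.nan
        )
    meta = {"protocol": "rate_mtf", "model": model.name, "seed": seed,
            "duration": duration}
    return (
        TuningCurve(f_grid, rates, meta),
        TuningCurve(f_grid, np.zeros(len(f_grid)), {**meta, "gain_db": gains}),
    )


def phase_tuning(
    model,
    f_m: float = 300.0,
    phase_grid: Sequence[float] = DEFAULT_PHASE_GRID,
    duration: float = 40.0,
    seed: int = 0,
    config: InputEnsembleConfig = InputEnsembleConfig(),
) -> TuningCurve:
    """Binaural AM phase tuning at modulation frequency ``f_m``.  The phase
    grid (cycles) must span one full envelope cycle."""
    rates = []
    for i, dphi in enumerate(phase_grid):
        stim = StimulusSpec.am_binaural(f_m=f_m, phase_diff=float(dphi),
                                        duration=duration)
        _, rate = _run_point(model, stim, config, seed, _PROTO_PHASE, i)
        rates.append(rate)
    meta = {"protocol": "phase_tuning", "model": model.name, "f_m": f_m,
            "seed": seed, "duration": duration}
    return TuningCurve(phase_grid, rates, meta)


def ild_tuning(
    model,
    spl_ipsi: float = 35.0,
    contra_grid: Sequence[float] = DEFAULT_CONTRA_GRID,
    duration: float = 40.0,
    seed: int = 0,
    config: InputEnsembleConfig = InputEnsembleConfig(),
) -> TuningCurve:
    """Binaural level tuning: rate vs. ILD = contra - ipsi (dB)."""
    rates = []
    for i, spl_c in enumerate(contra_grid):
        stim = StimulusSpec.tone_binaural(spl_ipsi=spl_ipsi,
                                          spl_contra=float(spl_c),
                                          duration=duration)
        _, rate = _run_point(model, stim, config, seed, _PROTO_ILD, i)
        rates.append(rate)
    ild = np.asarray(contra_grid, dtype=float) - spl_ipsi
    meta = {"protocol": "ild_tuning", "model": model.name, "spl_ipsi": spl_ipsi,
            "seed": seed, "duration": duration}
    return TuningCurve(ild, rates, meta)


# ---------------------------------------------------------------------------
# range scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Closed interval by default; ``lo_open`` encodes strict '> lo' bounds."""

    lo: float
    hi: float = np.inf
    lo_open: bool = False

    def __contains__(self, x: float) -> bool:
        ok_lo = x > self.lo if self.lo_open else x >= self.lo
        return ok_lo and x <= self.hi


@dataclass(frozen=True)
class RangeSpec:
    """Targeted and accepted spike-rate ranges for the nine calibration
    measures (three curves x peak/trough/depth)."""

    targeted: dict
    accepted: dict

    def __post_init__(self) -> None:
        if set(self.targeted) != set(self.accepted):
            raise ValueError("targeted and accepted must cover the same measures")


_MEASURES = [
    ("monaural", "peak"), ("monaural", "trough"), ("monaural", "depth"),
    ("phase", "peak"), ("phase", "trough"), ("phase", "depth"),
    ("ild", "peak"), ("ild", "trough"), ("ild", "depth"),
]

TABLE1_RANGES = RangeSpec(
    targeted={
        ("monaural", "peak"): Interval(120, 160),
        ("monaural", "trough"): Interval(0, 30),
        ("monaural", "depth"): Interval(110, lo_open=True),
        ("phase", "peak"): Interval(110, 140),
        ("phase", "trough"): Interval(10, 30),
        ("phase", "depth"): Interval(90, lo_open=True),
        ("ild", "peak"): Interval(110, 140),
        ("ild", "trough"): Interval(10, 30),
        ("ild", "depth"): Interval(90, lo_open=True),
    },
    accepted={
        ("monaural", "peak"): Interval(100, 180),
        ("monaural", "trough"): Interval(0, 50),
        ("monaural", "depth"): Interval(90, lo_open=True),
        ("phase", "peak"): Interval(90, 160),
        ("phase", "trough"): Interval(0, 40),
        ("phase", "depth"): Interval(70, lo_open=True),
        ("ild", "peak"): Interval(90, 160),
        ("ild", "trough"): Interval(0, 40),
        ("ild", "depth"): Interval(70, lo_open=True),
    },
)


@dataclass
class Score:
    n_targeted: int
    n_accepted: int
    values: dict
    hits: dict


def score_against_ranges(
    monaural: TuningStats,
    phase: TuningStats,
    ild: TuningStats,
    ranges: RangeSpec = TABLE1_RANGES,
) -> Score:
    """Count how many of the nine measures fall inside the targeted and
    accepted intervals."""
    stats = {"monaural": monaural, "phase": phase, "ild": ild}
    values, hits = {}, {}
    n_t = n_a = 0
    for curve, measure in _MEASURES:
        v = getattr(stats[curve], measure)
        in_t = v in ranges.targeted[(curve, measure)]
        in_a = v in ranges.accepted[(curve, measure)]
        values[(curve, measure)] = v
        hits[(curve, measure)] = (in_t, in_a)
        n_t += in_t
        n_a += in_a
    return Score(n_targeted=n_t, n_accepted=n_a, values=values, hits=hits)


def calibration_summary(
    model,
    duration: float = 40.0,
    seed: int = 0,
    config: InputEnsembleConfig = InputEnsembleConfig(),
    ranges: RangeSpec = TABLE1_RANGES,
) -> dict:
    """Run the three calibration protocols and score the model."""
    mtf, synch = rate_mtf(model, duration=duration, seed=seed, config=config)
    ph = phase_tuning(model, duration=duration, seed=seed, config=config)
    ild = ild_tuning(model, duration=duration, seed=seed, config=config)
    score = score_against_ranges(tuning_stats(mtf), tuning_stats(ph),
                                 tuning_stats(ild), ranges)
    return {"rate_mtf": mtf, "synch_mtf": synch, "phase": ph, "ild": ild,
            "score": score}


# ---------------------------------------------------------------------------
# membrane protocols (conductance-based models only)
# ---------------------------------------------------------------------------

def _require_membrane(model) -> None:
    if not getattr(model, "has_membrane", False):
        raise TypeError(
            f"model {getattr(model, 'name', model)!r} has no membrane; "
            "this protocol applies to conductance-based models only"
        )


def clamp_bias(
    model,
    v_clamp: float = -60.0,
    settle_ms: float = 600.0,
    na_enabled: bool = True,
    tol_mv: float = 0.01,
) -> float:
    """DC bias current (pA) that holds the settled membrane at ``v_clamp``,
    found by 1-D root finding on the settled potential."""
    _require_membrane(model)

    def settled_v(i_bias: float) -> float:
        try:
            res = model.integrate(
                duration_ms=settle_ms, i_ext=i_bias, spikes_enabled=False,
                v0=v_clamp, record=False, na_enabled=na_enabled,
            )
        except (ValueError, ZeroDivisionError):
            # divergence at an extreme bracket current: report a deflection
            # of the matching sign so the root stays bracketed
            return 1e6 if i_bias > 0 else -1e6
        return res.state[0] - v_clamp

    bias = optimize.brentq(settled_v, -5000.0, 5000.0, xtol=1e-3)
    if abs(settled_v(bias)) > tol_mv:
        raise RuntimeError("voltage clamp failed to converge")
    return float(bias)


def _clamped_state(model, v_clamp, bias, settle_ms, na_enabled):
    res = model.integrate(
        duration_ms=settle_ms, i_ext=bias, spikes_enabled=False, v0=v_clamp,
        record=False, na_enabled=na_enabled,
    )
    return res.state


def dc_input_resistance(
    model,
    v_clamp: float = -60.0,
    i_app: float = 10.0,
    settle_ms: float = 600.0,
    na_enabled: bool = False,
) -> float:
    """DC input resistance (MOhm): clamp at ``v_clamp`` by a bias current,
    apply ``i_app`` (pA) on top, and divide the settled deflection by the
    current.  Spike generators (and, by default, sodium channels) are
    disabled."""
    _require_membrane(model)
    bias = clamp_bias(model, v_clamp, settle_ms, na_enabled)
    state0 = _clamped_state(model, v_clamp, bias, settle_ms, na_enabled)
    v_base = state0[0]
    res = model.integrate(
        duration_ms=settle_ms, i_ext=bias + i_app, spikes_enabled=False,
        state0=state0, record=False, na_enabled=na_enabled,
    )
    # mV / nA = MOhm
    return float((res.state[0] - v_base) / (i_app * 1e-3))


def iv_curve(
    model,
    currents: Sequence[float] = np.arange(-500.0, 1501.0, 100.0),
    v_clamp: float = -60.0,
    settle_ms: float = 600.0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Steady-state I-V relationship from the -60 mV clamp, with spike
    mechanisms disabled (threshold detector off; g_Na = 0 for HH models).

    Returns ``(currents_pA, v_steady_mV, r_dc_MOhm)``.
    """
    _require_membrane(model)
    bias = clamp_bias(model, v_clamp, settle_ms, na_enabled=False)
    state0 = _clamped_state(model, v_clamp, bias, settle_ms, False)
    v_ss = []
    for i_app in currents:
        res = model.integrate(
            duration_ms=settle_ms, i_ext=bias + float(i_app),
            spikes_enabled=False, state0=state0, record=False,
            na_enabled=False,
        )
        v_ss.append(res.state[0])
    r_dc = dc_input_resistance(model, v_clamp, settle_ms=settle_ms)
    return np.asarray(currents, dtype=float), np.asarray(v_ss), r_dc


def impedance_profile(
    model,
    freqs: Sequence[float] = np.logspace(1, np.log10(40000.0), 13),
    v_clamp: float = -60.0,
    i_amp: float = 10.0,
    settle_ms: float = 200.0,
    n_cycles: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Membrane impedance R(f) in MOhm from sinusoidal current injections
    of amplitude ``i_amp`` pA around the -60 mV clamp:
    ``R(f) = (V_max - V_min) / (2 I_app)`` over the steady-state cycles."""
    _require_membrane(model)
    bias = clamp_bias(model, v_clamp)
    state0 = _clamped_state(model, v_clamp, bias, 600.0, True)
    dt = model.dt
    out = []
    for f in freqs:
        period_ms = 1000.0 / f
        dur = settle_ms + n_cycles * period_ms
        n_steps = int(round(dur / dt))
        t_ms = np.arange(n_steps) * dt
        i_arr = bias + i_amp * np.sin(2.0 * np.pi * f * t_ms * 1e-3)
        res = model.integrate(
            duration_ms=dur, i_ext=i_arr, spikes_enabled=False, state0=state0,
            record=True,
        )
        tail = res.trace.v[int(round(settle_ms / dt)):]
        out.append((tail.max() - tail.min()) / (2.0 * i_amp * 1e-3))
    return np.asarray(freqs, dtype=float), np.asarray(out)


def classify_step_response(
    model,
    amplitudes: Sequence[float] = np.arange(100.0, 1001.0, 100.0),
    step_ms: float = 30.0,
    pre_ms: float = 5.0,
    post_ms: float = 10.0,
) -> list:
    """Label the response to 30-ms step currents as 'no-spike', 'phasic' or
    'tonic'.  'Tonic' means spiking lasted until the step offset,
    operationalized as the last spike falling within one mean inter-spike
    interval of the offset; a single spike counts as phasic."""
    _require_membrane(model)
    rest = model.rest_state(400.0)
    dt = model.dt
    dur = pre_ms + step_ms + post_ms
    n_steps = int(round(dur / dt))
    t_ms = np.arange(n_steps) * dt
    labels = []
    for amp in amplitudes:
        i_arr = np.where((t_ms >= pre_ms) & (t_ms < pre_ms + step_ms),
                         float(amp), 0.0)
        res = model.integrate(
            duration_ms=dur, i_ext=i_arr, spikes_enabled=True,
            state0=rest.copy(), record=False,
        )
        spk_ms = res.spikes.times * 1e3
        spk_ms = spk_ms[(spk_ms >= pre_ms) & (spk_ms <= pre_ms + step_ms)]
        if spk_ms.size == 0:
            labels.append("no-spike")
        elif spk_ms.size == 1:
            labels.append("phasic")
        else:
            mean_isi = (spk_ms[-1] - spk_ms[0]) / (spk_ms.size - 1)
            off = pre_ms + step_ms
            labels.append("tonic" if off - spk_ms[-1] <= mean_isi else "phasic")
    return labels


# ---------------------------------------------------------------------------
# unitary PSP calibration
# ---------------------------------------------------------------------------

def unitary_psp(
    kind: str = "ex",
    syn: SynapticParams = SynapticParams(),
    membrane: PassiveIFParams = PassiveIFParams(),
    dt: float = 0.002,
    duration_ms: float = 40.0,
    spike_ms: float = 2.0,
) -> MembraneTrace:
    """Response of the spikeless RC calibration membrane to one synaptic
    event (the passive IF membrane without a threshold)."""
    if kind not in ("ex", "inh"):
        raise ValueError("kind must be 'ex' or 'inh'")
    model = PassiveIF(membrane, syn, dt)
    t = [spike_ms * 1e-3]
    inputs = SpikeTrainSet(
        excitatory=[t] if kind == "ex" else [],
        inhibitory=[t] if kind == "inh" else [],
        config=InputEnsembleConfig(m_ex=1 if kind == "ex" else 0,
                                   m_inh=0 if kind == "ex" else 1),
    )
    res = model.integrate(
        inputs=inputs, duration_ms=duration_ms, spikes_enabled=False,
        v0=membrane.e_l, record=True,
    )
    return res.trace


def psp_metrics(trace: MembraneTrace) -> Tuple[float, float]:
    """Amplitude (mV) and 5%-to-5% duration (ms) of a unitary PSP.

    The amplitude is the peak absolute deviation from the baseline (the
    first trace sample); the duration is the interval between the first
    and last crossings of 5% of the peak amplitude.  A flat trace has
    amplitude 0 and undefined (NaN) duration.
    """
    v = np.asarray(trace.v, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    dev = np.abs(v - v[0])
    amp = float(dev.max())
    if amp == 0.0:
        return 0.0, float("nan")
    above = np.nonzero(dev >= 0.05 * amp)[0]
    duration_ms = (trace.t[above[-1]] - trace.t[above[0]]) * 1e3
    return amp, float(duration_ms)
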