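"""Common input stage: phase-locked Poisson spike trains for LSO models.

An LSO (lateral superior olive) principal neuron receives 20 excitatory
fibers (spherical bushy cells of the ipsilateral AVCN) and 8 inhibitory
fibers (MNTB principal neurons driven by the contralateral ear).  Each
fiber is modeled as an inhomogeneous Poisson process.  For amplitude-
modulated (AM) tones the intensity is locked to the modulation frequency
``f_m`` through a von Mises density whose concentration ``k`` is chosen to
hit a prescribed vector strength; for unmodulated tones the intensity is a
level-dependent constant.  All models of the framework consume the same
ensemble so that, for a fixed seed, every neuron model sees bit-identical
inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "StimulusSpec",
    "InputEnsembleConfig",
    "SpikeTrain",
    "SpikeTrainSet",
    "am_mean_intensity",
    "target_vector_strength",
    "vs_from_concentration",
    "concentration_from_vs",
    "von_mises_density",
    "am_intensity",
    "level_intensity",
    "generate_inhomogeneous_poisson",
    "build_input_set",
]

#: Spontaneous rate of MNTB fibers under ipsilateral-only stimulation, spikes/s.
SPONT_RATE = 30.0

_AM_MODES = ("am_monaural", "am_binaural")
_MODES = _AM_MODES + ("tone_binaural",)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus description for one simulation run.

    Parameters
    ----------
    mode:
        ``am_monaural`` (ipsilateral AM tone), ``am_binaural`` (AM tones at
        both ears with an envelope phase difference) or ``tone_binaural``
        (unmodulated tones with independent levels at the two ears).
    f_m:
        Modulation frequency in Hz (AM modes only).
    phase_diff:
        Envelope phase difference in cycles, ``am_binaural`` only.  Positive
        values mean the inhibitory inputs *precede* the excitatory inputs.
    spl_ipsi, spl_contra:
        Sound levels in dB for ``tone_binaural``.
    duration:
        Stimulus duration in seconds.
    """

    mode: str
    duration: float
    f_m: Optional[float] = None
    phase_diff: float = 0.0
    spl_ipsi: Optional[float] = None
    spl_contra: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.mode in _AM_MODES:
            if self.f_m is None or not self.f_m > 0:
                raise ValueError("AM modes require f_m > 0")
        if self.mode == "tone_binaural":
            if self.spl_ipsi is None or self.spl_contra is None:
                raise ValueError("tone_binaural requires spl_ipsi and spl_contra")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def am_monaural(cls, f_m: float, duration: float) -> "StimulusSpec":
        return cls(mode="am_monaural", f_m=f_m, duration=duration)

    @classmethod
    def am_binaural(
        cls,
        f_m: float,
        phase_diff: float,
        duration: float,
        phase_unit: str = "cycles",
    ) -> "StimulusSpec":
        """Binaural AM stimulus.  ``phase_diff`` may be given in envelope
        cycles or in milliseconds (converted as ``cycles = ms * f_m / 1000``);
        it is stored in cycles."""
        if phase_unit == "ms":
            phase_diff = phase_diff * f_m / 1000.0
        elif phase_unit != "cycles":
            raise ValueError("phase_unit must be 'cycles' or 'ms'")
        return cls(mode="am_binaural", f_m=f_m, phase_diff=phase_diff, duration=duration)

    @classmethod
    def tone_binaural(
        cls, spl_ipsi: float, spl_contra: float, duration: float
    ) -> "StimulusSpec":
        return cls(
            mode="tone_binaural",
            spl_ipsi=spl_ipsi,
            spl_contra=spl_contra,
            duration=duration,
        )

    @property
    def ild(self) -> float:
        """Interaural level difference, contra minus ipsi (dB)."""
        if self.mode != "tone_binaural":
            raise ValueError("ILD is defined for tone_binaural stimuli only")
        return self.spl_contra - self.spl_ipsi

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


@dataclass(frozen=True)
class InputEnsembleConfig:
    """Fiber counts and spontaneous rate of the input ensemble."""

    m_ex: int = 20
    m_inh: int = 8
    spont_rate: float = SPONT_RATE

    def __post_init__(self) -> None:
        if self.m_ex < 0 or self.m_inh < 0 or self.spont_rate < 0:
            raise ValueError("fiber counts and spontaneous rate must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InputEnsembleConfig":
        return cls(**d)


class SpikeTrain:
    """A sorted sequence of spike times of one fiber, in seconds."""

    __slots__ = ("times",)

    def __init__(self, times: Sequence[float]):
        t = np.asarray(times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted")
        self.times = t

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        return isinstance(other, SpikeTrain) and np.array_equal(self.times, other.times)

    def __repr__(self) -> str:
        return f"SpikeTrain(n={len(self)})"

    def rate(self, duration: float) -> float:
        """Mean firing rate over ``duration`` seconds."""
        return len(self) / duration


@dataclass
class SpikeTrainSet:
    """The full input ensemble: excitatory and inhibitory fiber trains."""

    excitatory: list
    inhibitory: list
    stimulus: Optional[StimulusSpec] = None
    config: InputEnsembleConfig = field(default_factory=InputEnsembleConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.excitatory = [
            t if isinstance(t, SpikeTrain) else SpikeTrain(t) for t in self.excitatory
        ]
        self.inhibitory = [
            t if isinstance(t, SpikeTrain) else SpikeTrain(t) for t in self.inhibitory
        ]

    @property
    def duration(self) -> Optional[float]:
        return self.stimulus.duration if self.stimulus is not None else None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeTrainSet)
            and self.excitatory == other.excitatory
            and self.inhibitory == other.inhibitory
        )


# ---------------------------------------------------------------------------
# intensity functions (rates in spikes/s, f_m in Hz, SPL in dB)
# ---------------------------------------------------------------------------

def am_mean_intensity(f_m: float) -> float:
    """Mean fiber intensity for an AM tone: ``lambda_1 = 180 - 0.03 f_m``."""
    f_m = float(f_m)
    if f_m < 0:
        raise ValueError("f_m must be non-negative")
    if f_m > 1200:
        warnings.warn("f_m above 1200 Hz extrapolates the linear intensity fit")
    return 180.0 - 0.03 * f_m


def target_vector_strength(f_m: float) -> float:
    """Target phase-locking of the input fibers as a function of ``f_m``.

    ``VS(f_m) = 0.65 (1 - e^{(f_m-2000)/500}) / (1 + e^{(f_m-2000)/500})``,
    a strictly decreasing sigmoid that vanishes at 2 kHz.  Frequencies at or
    above 2 kHz are clamped to zero with a warning.
    """
    f_m = float(f_m)
    if not f_m > 0:
        raise ValueError("f_m must be positive")
    if f_m >= 2000:
        warnings.warn("no phase-locking above 2 kHz; vector strength clamped to 0")
        return 0.0
    e = np.exp((f_m - 2000.0) / 500.0)
    return 0.65 * (1.0 - e) / (1.0 + e)


def vs_from_concentration(k: float) -> float:
    """Vector strength of a von Mises phase distribution: ``I1(k)/I0(k)``."""
    if k < 0:
        raise ValueError("concentration must be >= 0")
    if k == 0.0:
        return 0.0
    # exponentially scaled Bessels avoid overflow for large k
    return special.ive(1, k) / special.ive(0, k)


def concentration_from_vs(vs: float, tol: float = 1e-12) -> float:
    """Invert ``VS(k) = I1(k)/I0(k)`` by bracketed root finding.

    The ratio is strictly increasing from 0 (at k=0) towards 1, so bisection
    on [0, 1e4] is robust for any attainable vector strength.
    """
    vs = float(vs)
    if not 0.0 <= vs < 1.0:
        raise ValueError("vector strength must lie in [0, 1)")
    if vs == 0.0:
        return 0.0
    k = optimize.brentq(lambda kk: vs_from_concentration(kk) - vs, 0.0, 1e4, xtol=tol)
    return float(k)


def von_mises_density(x, k: float):
    """von Mises density ``p_k(x) = exp(k cos x) / (2 pi I0(k))`` (1/radian)."""
    if k < 0:
        raise ValueError("concentration must be >= 0")
    x = np.asarray(x, dtype=float)
    # exp(k cos x) / I0(k) = exp(k (cos x - 1)) / ive(0, k)
    out = np.exp(k * (np.cos(x) - 1.0)) / (2.0 * np.pi * special.ive(0, k))
    return out if out.ndim else float(out)


def am_intensity(t, f_m: float, k: float, lambda1: float, phase_offset: float = 0.0):
    """Phase-locked Poisson intensity ``lambda(t) = 2 pi lambda1 p_k(2 pi f_m t)``.

    ``phase_offset`` (in cycles) delays the locking phase: the intensity
    peaks where the modulation phase equals the offset.  The time average
    over one modulation period is exactly ``lambda1``.
    """
    t = np.asarray(t, dtype=float)
    x = 2.0 * np.pi * (f_m * t - phase_offset)
    out = 2.0 * np.pi * lambda1 * von_mises_density(x, k)
    return out if np.ndim(out) else float(out)


def level_intensity(spl) -> float:
    """Level-dependent fiber intensity for unmodulated tones.

    A sigmoid ``30 + 240 / (1 + exp(-(SPL-20)/6))`` rising from the 30
    spikes/s spontaneous floor to 270 spikes/s at saturation.
    """
    spl = np.asarray(spl, dtype=float)
    out = 30.0 + 240.0 * special.expit((spl - 20.0) / 6.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Poisson generation
# ---------------------------------------------------------------------------

def generate_inhomogeneous_poisson(
    intensity: Callable[[np.ndarray], np.ndarray],
    duration: float,
    rate_max: float,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Sample an inhomogeneous Poisson train by Lewis-Shedler thinning.

    ``rate_max`` must be a true upper bound of ``intensity`` on
    ``[0, duration]``; candidate events are drawn from a homogeneous process
    at ``rate_max`` and retained with probability ``intensity(t)/rate_max``.
    """
    if not np.isfinite(rate_max) or rate_max < 0:
        raise ValueError("rate_max must be finite and non-negative")
    if rate_max == 0.0:
        return SpikeTrain(np.empty(0))
    n = rng.poisson(rate_max * duration)
    t = np.sort(rng.random(n)) * duration
    u = rng.random(n)
    lam = np.asarray(intensity(t), dtype=float)
    if np.any(lam > rate_max * (1.0 + 1e-9)):
        raise ValueError("intensity exceeds the stated envelope rate_max")
    return SpikeTrain(t[u * rate_max < lam])


def _fiber_rng(seed, spawn_key: tuple) -> np.random.Generator:
    """Counter-keyed substream: independent of other fibers, stable under
    changes of the ensemble size."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def build_input_set(
    stimulus: StimulusSpec,
    config: InputEnsembleConfig = InputEnsembleConfig(),
    seed: int = 0,
    spawn_prefix: tuple = (),
) -> SpikeTrainSet:
    """Generate the full excitatory + inhibitory input ensemble.

    * ``am_monaural`` -- excitatory fibers phase-locked with mean rate
      ``lambda1(f_m)`` and vector strength ``VS(f_m)``; inhibitory fibers
      homogeneous at the spontaneous rate (MNTB activity without
      contralateral drive).
    * ``am_binaural`` -- both populations phase-locked at ``lambda1(f_m)``;
      the inhibitory locking phase is shifted so that a positive
      ``phase_diff`` makes inhibition lead excitation.
    * ``tone_binaural`` -- homogeneous trains at ``lambda(spl_ipsi)``
      (excitation) and ``lambda(spl_contra)`` (inhibition).

    Each fiber draws from its own RNG substream derived from ``seed``, so
    equal seeds give bit-identical ensembles (all neuron models can be fed
    the very same input) and changing one fiber count does not perturb the
    remaining streams.
    """
    dur = stimulus.duration

    def _am_fiber(rng, lambda1, k, phase_offset):
        lam_max = 2.0 * np.pi * lambda1 * von_mises_density(0.0, k)
        return generate_inhomogeneous_poisson(
            lambda t: am_intensity(t, stimulus.f_m, k, lambda1, phase_offset),
            dur,
            lam_max,
            rng,
        )

    def _flat_fiber(rng, rate):
        return generate_inhomogeneous_poisson(
            lambda t: np.full_like(t, rate), dur, rate, rng
        )

    ex, inh = [], []
    if stimulus.mode in _AM_MODES:
        lambda1 = am_mean_intensity(stimulus.f_m)
        k = concentration_from_vs(target_vector_strength(stimulus.f_m))
        for m in range(config.m_ex):
            ex.append(_am_fiber(_fiber_rng(seed, spawn_prefix + (0, m)), lambda1, k, 0.0))
        for m in range(config.m_inh):
            rng = _fiber_rng(seed, spawn_prefix + (1, m))
            if stimulus.mode == "am_binaural":
                # negative offset shifts the inhibitory peak earlier in time
                inh.append(_am_fiber(rng, lambda1, k, -stimulus.phase_diff))
            else:
                inh.append(_flat_fiber(rng, config.spont_rate))
    else:  # tone_binaural
        rate_ex = level_intensity(stimulus.spl_ipsi)
        rate_inh = level_intensity(stimulus.spl_contra)
        for m in range(config.m_ex):
            ex.append(_flat_fiber(_fiber_rng(seed, spawn_prefix + (0, m)), rate_ex))
        for m in range(config.m_inh):
            inh.append(_flat_fiber(_fiber_rng(seed, spawn_prefix + (1, m)), rate_inh))

    return SpikeTrainSet(
        excitatory=ex, inhibitory=inh, stimulus=stimulus, config=config, seed=seed
    )
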