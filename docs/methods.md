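# Methods

## The modeling framework

An LSO principal neuron is driven by two spike-train populations: 20
excitatory fibers (spherical bushy cells of the ipsilateral AVCN) and 8
inhibitory fibers (MNTB principal neurons excited by the contralateral
ear). The framework fixes this input stage and varies only the neuron
model, so that differences in output tuning are attributable to the model
and not to the stimulus. All models are single-compartment and noise-free:
trial-to-trial variability comes exclusively from the stochastic inputs.

### Input stage

Each fiber is an inhomogeneous Poisson process sampled by Lewis–Shedler
thinning with the exact intensity maximum 2π λ₁ p_k(0) as the envelope.
Three stimulus modes exist:

* **am_monaural** — excitatory fibers phase-locked at mean rate
  λ₁(f_m) = 180 − 0.03 f_m spikes/s with vector strength
  VS(f_m) = 0.65 (1 − e^{(f_m−2000)/500})/(1 + e^{(f_m−2000)/500});
  inhibitory fibers fire homogeneously at the 30 spikes/s spontaneous rate
  (no contralateral drive). No spontaneous floor is added to the excitatory
  rate: λ₁ itself is the excitatory rate.
* **am_binaural** — both populations phase-locked at λ₁(f_m); the
  inhibitory locking phase is shifted so that a *positive* phase difference
  (stored internally in cycles; a millisecond interface converts by
  Δφ = Δt·f_m) makes inhibition *lead* excitation.
* **tone_binaural** — homogeneous trains at λ(SPL) = 30 + 240/(1 +
  e^{−(SPL−20)/6}) evaluated at the ipsilateral level for excitation and
  the contralateral level for inhibition.

The phase-locking profile is imposed through a von Mises density whose
concentration k is recovered from the target VS by bracketed root finding
(Brent on [0, 10⁴]; the ratio I₁(k)/I₀(k) is strictly increasing, and the
exponentially-scaled Bessel ratio is overflow-safe), to |VS(k) − VS| <
10⁻¹². Every fiber owns an RNG substream keyed by
`SeedSequence(seed, spawn_key=(…, population, fiber))`, so equal seeds give
bit-identical ensembles — every neuron model sees the same spikes — and
changing a fiber count does not perturb the remaining streams.

### Shot-noise models

The **coincidence counting model** (refractory period T_ref = 1.6 ms,
threshold θ = 8, excitatory window W_ex = 0.8 ms, inhibition amplitude
H = 2, inhibition window W_inh = 1.6 ms) counts excitatory spikes in the
half-open window (t − W_ex, t] and subtracts H per inhibitory spike in
(t − W_inh, t]; an output spike occurs when the count reaches θ and at
least T_ref has elapsed since the previous output. Counting at excitatory
arrival times only is sufficient because the count can newly reach the
positive threshold only when an excitatory spike enters the window. The
half-open convention (a spike exactly W in the past has left the window;
simultaneous spikes all count) makes the rule deterministic and
order-independent; window boundaries carry a 10⁻⁹ ms guard so float
round-off cannot flip a boundary decision. Subtracting counts is
mathematically identical to elevating the threshold by H per inhibitory
event.

The **Stein models** replace the rectangular window by decaying kernels —
exponential (θ = 5.5, τ_ex = 0.70 ms, H = 1.8, τ_inh = 0.98 ms) or alpha
(θ = 7.3, τ_ex = 0.45 ms, H = 1.7, τ_inh = 0.63 ms), excitatory amplitude
fixed at 1 — summed linearly into a virtual membrane potential. The sum is
maintained by exact per-step exponential recursions (one auxiliary state
per population for exponential kernels, two for alpha kernels), so no
spike history is stored and the subthreshold trace equals the direct
convolution to machine precision. At an output spike all kernel state is
cleared and the potential is clamped to zero for T_ref; threshold
detection resumes exactly T_ref after the spike. Whether kernels started
by inputs arriving *during* the refractory period persist afterwards is
not constrained by the model definition; they persist by default, and a
`refractory_inputs="discard"` flag provides the alternative reading.

### Conductance-based models

Units are canonical ms/mV/nS/pA/pF (nS·mV = pA, pF/nS = ms), which makes
the Euler update dimension-safe; the active IF spike-current amplitudes
quoted in nA are converted to pA at load time. Synapses are alpha
conductances (peak A_ex = 3.5 nS at τ_ex = 0.16 ms, A_inh = 12 nS at
τ_inh = 0.32 ms, E_ex = 0 mV, E_inh = −75 mV; the original Wang–Colburn
configuration uses E_inh = −70 mV), driving currents g(t)(E_rev − V).

* **Passive IF**: RC membrane (C = 24 pF, g_L = 26.4 nS, E_L = −60 mV)
  with threshold −45.3 mV; on a spike V is held at the −60 mV reset for
  T_ref = 1.6 ms.
* **Active IF**: adds a KLVA conductance (g_KL = 21.6 nS, E_K = −75 mV)
  with first-order gate d(V) (α = 0.5 e^{(V+50)/16}, β symmetric),
  g_L = 14.4 nS, E_L = −56 mV, threshold −45.8 mV. Instead of a reset, a
  spike-associated current 24 e^{−t/0.15} − 12 e^{−t/0.30} nA (exact
  two-exponential recursion) is injected at each threshold crossing and
  spike initiation is suppressed for T_ref; the membrane is never clamped.
  Overlapping injections would sum, but cannot occur because T_ref exceeds
  the current's effective duration.
* **Wang–Colburn (original/adjusted)**: leak + KLVA (w⁴z) + KHVA
  (0.85 n² + 0.15 p) + Na (m³h) with Rothman–Manis kinetics; all gating
  rates are multiplied by φ = Q10^{(T−22)/10} = 3^{1.5} and evaluated at
  V − V_shift (0 mV original, +5 mV adjusted). Spikes are detected by the
  −30/−45 mV hysteresis rule (counted at the upward −30 mV crossing); no
  explicit refractory period is imposed. The adjusted parameter set
  (C = 24 pF, g_L = 24 nS, g_KL = 15 nS, g_KH = 440 nS, g_Na = 4400 nS,
  E_L = −60 mV, E_K = −75 mV) restores binaural level coding that the
  original set (31.4/31.4/85/1200/8000, E_L = −65 mV, E_K = −70 mV)
  suppresses through KLVA activation and Na inactivation.

Integration is explicit forward Euler at dt = 2 µs (configurable; larger
steps warn). Spike times are the first grid point at or above threshold —
no sub-step interpolation, consistent with the fixed-step scheme. Gate
variables use forward Euler as well; if a step would overshoot the gate's
steady state (possible only at non-physiological voltages reached while
bracketing clamp currents) the gate snaps to its steady state, which keeps
the root-finder's trial integrations finite without affecting any
physiological trajectory. Before every protocol the membrane settles
200 ms (1000 ms for resting-potential reads, generous against the slowest
gate, τ_z/φ ≈ 10² ms) with gates initialized at their steady state for the
starting voltage; reported traces exclude the settle window.

### Protocols and measures

* **Tuning curves**: rate-MTF over f_m = 50–1200 Hz, binaural phase tuning
  at 300 Hz (and 150/450 Hz for characterization), ILD tuning at
  ipsilateral 35 dB with contralateral −10…+50 dB. Grid steps are our
  choice where the protocol only states spans: 50 Hz for f_m, 16 evenly
  spaced phases per cycle, 5 dB for contralateral level. Rates are mean
  counts over 40 s per stimulus point; peaks and troughs are grid extrema
  (no interpolation). Each stimulus point derives its seed from the master
  seed and the point index, so any point is independently re-runnable.
* **Scoring**: the nine measures (peak/trough/depth × three curves) are
  compared with targeted and accepted intervals (monaural peak 120–160
  targeted / 100–180 accepted, trough 0–30/0–50, depth >110/>90; binaural
  phase and ILD peak 110–140/90–160, trough 10–30/0–40, depth >90/>70,
  spikes/s). Closed intervals — a value exactly on a boundary counts as
  inside — except the depth bounds, which are strict as stated.
* **Membrane characterization**: voltage clamp is implemented as a DC bias
  current found by Brent root finding on the settled potential
  (|V − V_clamp| < 0.01 mV). DC input resistance is the settled deflection
  under +10 pA divided by the current, from the −60 mV clamp with spike
  generators off and (for HH models) g_Na = 0. Impedance uses 10 pA
  sinusoids, reading (V_max − V_min)/(2 I) over the last 3 cycles after a
  200 ms settle. Step responses (30 ms, 0–1 nA) are labelled tonic when
  the last spike falls within one mean inter-spike interval of the step
  offset, phasic otherwise (a single spike is phasic), no-spike when
  silent. Unitary PSPs are measured on the passive-IF membrane without a
  threshold; the duration is the interval between the two crossings of 5%
  of the peak deviation.

## What the generator emulates — and what it does not

The synthetic inputs reproduce the mean rate, the level dependence and the
frequency-dependent phase locking of bushy-cell and MNTB spike trains, with
statistically independent fibers. They do not model refractoriness or
non-Poisson interval statistics of real auditory nerve fibers, across-fiber
correlation, adaptation, or a cochlear front-end; passing tests therefore
validate the models' excitatory–inhibitory computation under idealized
Poisson drive, not their behavior with natural stimuli.

## Numerical choices and limitations

* Forward Euler at 2 µs is first-order; the passive-IF step response
  converges at observed order 1 to the RC closed form, and the unit suite
  checks Stein recursions against direct convolution to 10⁻⁹.
* Stochastic tuning numbers carry sampling error ≈ √(rate/40 s) per point
  (≈ 1.9 spikes/s at 140 spikes/s); curve extrema inherit a small
  selection bias of the same order.
* The active IF relaxation can transiently overshoot rest by a fraction of
  a millivolt because the KLVA gate lags the potential; this is a property
  of the two-variable system, not a numerical artifact.
* The DC input resistance of the original Wang–Colburn model is measured
  at the −60 mV clamp per the standard protocol, where it evaluates to
  ≈ 20.9 MΩ; measured at its ≈ −65 mV rest instead, the linearized
  conductance is smaller and the resistance higher, so the −60 mV reading
  is the one consistent with the ≈ 21 MΩ characterization.
* Wall-clock benchmarking across models is out of scope (hardware
  dependent); so are PSTH chopping analyses, multi-compartment extensions
  and additional channel types.
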