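# olivesim

Point-neuron simulation toolkit for the **lateral superior olive (LSO)**,
the auditory brainstem nucleus that compares ipsilateral excitation with
contralateral-driven inhibition to encode interaural level and envelope-time
differences (ILD/ITD). The package provides:

* a common **input stage**: 20 excitatory (AVCN bushy-cell-like) and 8
  inhibitory (MNTB-like) fibers simulated as inhomogeneous Poisson
  processes. For amplitude-modulated (AM) tones the intensity is locked to
  the modulation frequency *f*<sub>m</sub> via a von Mises density,
  λ(t) = 2π λ₁(*f*<sub>m</sub>) p<sub>k</sub>(2π *f*<sub>m</sub> t), with
  λ₁(*f*<sub>m</sub>) = 180 − 0.03 *f*<sub>m</sub> spikes/s and the
  concentration *k* inverted from a target vector strength
  VS(*k*) = I₁(*k*)/I₀(*k*); for unmodulated tones the rate follows a level
  sigmoid λ(SPL) = 30 + 240/(1 + e^{−(SPL−20)/6}) spikes/s;
* **seven LSO neuron models** of increasing biophysical complexity, all
  consuming the same input ensemble:
  coincidence counting, exponential Stein, alpha Stein (threshold models on
  kernel-weighted input counts), passive and active integrate-and-fire, and
  the original and adjusted Wang–Colburn Hodgkin–Huxley-type models with
  Rothman–Manis channel kinetics (leak, KLVA, KHVA, Na);
* **output measures and protocols**: rate and synchrony modulation transfer
  functions, binaural envelope-phase tuning, ILD tuning, targeted/accepted
  range scoring, membrane impedance, I–V curves with DC input resistance,
  phasic/tonic step-response classification, and unitary PSP calibration.

All membranes are integrated by explicit forward Euler at a 2 µs step
(numba-compiled inner loops), and every stochastic quantity derives from a
single master seed through counter-keyed substreams, so identical seeds
yield bit-identical results across models.

## Worked example

```python
from olivesim import get_model
from olivesim.metrics import rate_mtf, tuning_stats

model = get_model("coincidence")        # threshold 8, window 0.8 ms
mtf, synch = rate_mtf(model, duration=40.0, seed=1)
stats = tuning_stats(mtf)
print(f"peak {stats.peak:.1f} spikes/s at {mtf.x[mtf.rate.argmax()]:.0f} Hz, "
      f"trough {stats.trough:.1f}, depth {stats.depth:.1f}")
```

prints

```
peak 140.0 spikes/s at 250 Hz, trough 8.8, depth 131.2
```

i.e. a band-pass AM tuning curve whose peak lies in the 200–300 Hz region:
at low modulation frequencies the phase-locked excitatory volleys are broad
and rarely reach 8 coincident inputs within 0.8 ms, at high frequencies
phase-locking (and the mean rate) declines, and in between the sharpened
volleys drive the coincidence detector best. The active integrate-and-fire
model scores 9 of 9 targeted tuning ranges under the same protocol:

```python
from olivesim.metrics import calibration_summary
summary = calibration_summary(get_model("if_active"), duration=40.0, seed=1)
print(summary["score"].n_targeted)      # -> 9
```

A command-line interface wraps the same protocols:

```sh
olivesim run --model wc_adjusted --protocol ild_tuning --seed 1 --out results/
```

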