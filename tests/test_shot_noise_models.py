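"""Shot-noise model tests: kernels, the coincidence counting rule against
a brute-force grid oracle, and the Stein models against direct-convolution
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_ensemble
from olivesim.fixtures import make_fixture
from olivesim.input_stage import InputEnsembleConfig, SpikeTrain, SpikeTrainSet, \
    StimulusSpec, build_input_set
from olivesim.shot_noise_models import (
    CoincidenceParams,
    SteinParams,
    alpha_kernel,
    exp_kernel,
    run_coincidence_counting,
    run_stein,
)

MS = 1e-3


def _ensemble(ex, inh):
    return SpikeTrainSet(
        excitatory=[SpikeTrain(np.asarray(t) * MS) for t in ex],
        inhibitory=[SpikeTrain(np.asarray(t) * MS) for t in inh],
        config=InputEnsembleConfig(m_ex=len(ex), m_inh=len(inh), spont_rate=0.0),
    )


class TestKernels:
    @given(st.floats(0.05, 10.0), st.floats(0.1, 5.0))
    @settings(derandomize=True, max_examples=30)
    def test_exp_kernel_shape(self, tau, amp):
        assert exp_kernel(0.0, tau, amp) == pytest.approx(amp)
        assert exp_kernel(-1e-9, tau, amp) == 0.0
        assert exp_kernel(tau, tau, amp) == pytest.approx(amp / np.e)

    @given(st.floats(0.05, 10.0), st.floats(0.1, 5.0))
    @settings(derandomize=True, max_examples=30)
    def test_alpha_kernel_shape(self, tau, amp):
        assert alpha_kernel(tau, tau, amp) == pytest.approx(amp)
        assert alpha_kernel(0.0, tau, amp) == 0.0
        assert alpha_kernel(-1e-9, tau, amp) == 0.0
        # peak at t = tau
        t = np.linspace(0, 6 * tau, 200)
        assert np.all(alpha_kernel(t, tau, amp) <= amp * (1 + 1e-12))


def coincidence_grid_oracle(inputs, params, duration_ms=12.0):
    """Evaluate the coincidence count C(t) by brute force on a 1-us grid at
    every excitatory arrival and apply threshold + refractoriness."""
    ex = np.concatenate([tr.times for tr in inputs.excitatory]) * 1e3
    inh = np.concatenate([tr.times for tr in inputs.inhibitory]) * 1e3 \
        if inputs.inhibitory else np.empty(0)
    ex.sort()
    grid = np.round(np.arange(0, duration_ms, 1e-3), 6)
    out, last = [], -np.inf
    ex_r = np.round(ex, 6)
    for t in grid:
        if not np.any(ex_r == t):
            continue
        c = np.sum((ex >= t - params.w_ex + 1e-9) & (ex <= t))
        c -= params.h * np.sum((inh >= t - params.w_inh + 1e-9) & (inh <= t))
        if c >= params.theta and t - last >= params.t_ref - 1e-9:
            out.append(t)
            last = t
    return np.asarray(out)


class TestCoincidenceCounting:
    def test_threshold_count_fires(self):
        out = run_coincidence_counting(make_fixture("eight_coincident"))
        assert np.allclose(out.times, [1.0 * MS])

    def test_inhibition_subtracts_counts(self):
        # 8 - H*1 = 6 < theta: the preceding inhibitory spike blocks output
        out = run_coincidence_counting(make_fixture("eight_with_inhibition"))
        assert len(out) == 0

    def test_refractory_discards_second_cluster(self):
        # two suprathreshold clusters 1 ms apart, T_ref = 1.6 ms
        out = run_coincidence_counting(make_fixture("cluster_pair_1ms"))
        assert np.allclose(out.times, [1.0 * MS])

    def test_spike_exactly_window_ago_has_left_window(self):
        # (t - W, t] is half-open: a spike exactly W_ex in the past no
        # longer counts towards the coincidence
        params = CoincidenceParams(theta=2, h=0)
        inputs = _ensemble([[1.0], [1.8]], [])
        assert len(run_coincidence_counting(inputs, params)) == 0
        inputs = _ensemble([[1.0], [1.7999]], [])
        assert len(run_coincidence_counting(inputs, params)) == 1

    def test_matches_grid_oracle_on_random_inputs(self, rng):
        params = CoincidenceParams(theta=3, h=2)
        for _ in range(25):
            inputs = random_ensemble(rng, n_ex=4, n_inh=2, n_spikes=7)
            got = run_coincidence_counting(inputs, params).times * 1e3
            want = coincidence_grid_oracle(inputs, params)
            assert np.allclose(np.round(got, 6), want), (got, want)

    def test_extra_excitation_never_delays_first_spike(self, rng):
        params = CoincidenceParams(theta=3, h=2)
        for _ in range(20):
            inputs = random_ensemble(rng, n_ex=3, n_inh=1, n_spikes=6)
            base = run_coincidence_counting(inputs, params)
            t_new = float(np.round(rng.random() * 10.0, 3)) * MS
            aug = SpikeTrainSet(
                excitatory=inputs.excitatory + [SpikeTrain([t_new])],
                inhibitory=inputs.inhibitory,
                config=InputEnsembleConfig(m_ex=4, m_inh=1, spont_rate=0.0),
            )
            more = run_coincidence_counting(aug, params)
            if len(base):
                assert len(more) and more.times[0] <= base.times[0] + 1e-12

    def test_doubling_h_without_inhibition_changes_nothing(self, rng):
        inputs = random_ensemble(rng, n_ex=5, n_inh=0, n_spikes=8)
        a = run_coincidence_counting(inputs, CoincidenceParams(theta=3, h=2))
        b = run_coincidence_counting(inputs, CoincidenceParams(theta=3, h=4))
        assert a == b

    def test_integer_threshold_enforced(self):
        with pytest.raises(ValueError):
            CoincidenceParams(theta=7.5)


def stein_convolution_oracle(inputs, params, duration_ms, dt=1e-3):
    """Direct kernel-sum evaluation with reset-and-clamp semantics."""
    kern = exp_kernel if params.kernel_kind == "exponential" else alpha_kernel
    ex = np.sort(np.concatenate([tr.times for tr in inputs.excitatory] or [[]])) * 1e3
    inh = np.sort(np.concatenate([tr.times for tr in inputs.inhibitory] or [[]])) * 1e3
    grid = np.arange(int(round(duration_ms / dt))) * dt

    def free_v(t, ex_keep, inh_keep):
        v = np.zeros_like(t)
        for s in ex_keep:
            v += kern(t - s, params.tau_ex)
        for s in inh_keep:
            v -= params.h * kern(t - s, params.tau_inh)
        return v

    spikes = []
    t_start = 0.0
    ex_k, inh_k = ex, inh
    while True:
        v = free_v(grid, ex_k, inh_k)
        live = grid >= t_start
        idx = np.nonzero(live & (v >= params.theta - 1e-12))[0]
        if idx.size == 0:
            return np.asarray(spikes)
        t_sp = grid[idx[0]]
        spikes.append(t_sp)
        t_start = t_sp + params.t_ref - 1e-9
        # state cleared at the spike; inputs during refractoriness persist
        ex_k = ex_k[ex_k > t_sp]
        inh_k = inh_k[inh_k > t_sp]


class TestStein:
    def test_six_simultaneous_inputs_fire_immediately(self):
        out, _ = run_stein(make_fixture("six_coincident"), duration_ms=5.0)
        assert np.allclose(out.times, [1.0 * MS])

    def test_five_simultaneous_inputs_stay_subthreshold(self):
        out, trace = run_stein(make_fixture("five_coincident"), duration_ms=5.0)
        assert len(out) == 0
        assert trace.v.max() == pytest.approx(5.0)

    def test_simultaneous_inhibition_cancels(self):
        out, trace = run_stein(make_fixture("ex_plus_inh_simultaneous"),
                               duration_ms=5.0)
        assert len(out) == 0
        assert trace.v.min() == pytest.approx(1.0 - 1.8)

    def test_virtual_potential_zero_during_refractoriness(self):
        _, trace = run_stein(make_fixture("six_coincident"), duration_ms=5.0)
        t_ms = trace.t * 1e3
        refr = (t_ms >= 1.0) & (t_ms < 1.0 + 1.6)
        assert np.all(trace.v[refr] == 0.0)

    @pytest.mark.parametrize("params", [SteinParams.exponential(), SteinParams.alpha()],
                             ids=["exponential", "alpha"])
    def test_subthreshold_linearity_vs_direct_convolution(self, params, rng):
        inputs = random_ensemble(rng, n_ex=3, n_inh=2, n_spikes=6)
        inf_params = SteinParams(kernel_kind=params.kernel_kind, theta=np.inf,
                                 tau_ex=params.tau_ex, h=params.h,
                                 tau_inh=params.tau_inh)
        _, trace = run_stein(inputs, inf_params, dt=1e-3, duration_ms=12.0)
        want = stein_convolution_oracle(inputs, inf_params, 12.0)
        assert want.size == 0
        kern = exp_kernel if params.kernel_kind == "exponential" else alpha_kernel
        grid = trace.t * 1e3
        v = np.zeros_like(grid)
        for tr in inputs.excitatory:
            for s in tr.times * 1e3:
                v += kern(grid - s, params.tau_ex)
        for tr in inputs.inhibitory:
            for s in tr.times * 1e3:
                v -= params.h * kern(grid - s, params.tau_inh)
        assert np.max(np.abs(trace.v - v)) < 1e-9

    @pytest.mark.parametrize("params", [SteinParams.exponential(), SteinParams.alpha()],
                             ids=["exponential", "alpha"])
    def test_spike_times_match_convolution_oracle(self, params, rng):
        for _ in range(10):
            inputs = random_ensemble(rng, n_ex=6, n_inh=2, n_spikes=8)
            lowered = SteinParams(kernel_kind=params.kernel_kind, theta=2.5,
                                  tau_ex=params.tau_ex, h=params.h,
                                  tau_inh=params.tau_inh)
            got, _ = run_stein(inputs, lowered, dt=1e-3, duration_ms=12.0,
                               record_trace=False)
            want = stein_convolution_oracle(inputs, lowered, 12.0)
            assert got.times.size == want.size
            assert np.allclose(got.times * 1e3, want, atol=1.1e-3)

    def test_refractory_inputs_persist_by_default(self):
        # a suprathreshold volley arriving during the refractory period
        # persists and can trigger a spike right after it ends
        inputs = _ensemble([[1.0, 2.5]] * 8, [])
        persist, _ = run_stein(inputs, duration_ms=8.0)
        discard, _ = run_stein(inputs, duration_ms=8.0,
                               refractory_inputs="discard")
        assert len(persist) == 2 and len(discard) == 1
        assert persist.times[1] * 1e3 == pytest.approx(2.6, abs=0.01)

    def test_output_isi_respects_refractory_period(self):
        stim = StimulusSpec.am_monaural(300.0, duration=2.0)
        inputs = build_input_set(stim, seed=9)
        for params in (SteinParams.exponential(), SteinParams.alpha()):
            out, _ = run_stein(inputs, params, record_trace=False)
            if len(out) > 1:
                assert np.min(np.diff(out.times)) * 1e3 >= params.t_ref - 1e-9
        coinc = run_coincidence_counting(inputs)
        if len(coinc) > 1:
            assert np.min(np.diff(coinc.times)) * 1e3 >= 1.6 - 1e-9
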