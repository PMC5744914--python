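"""Input-stage tests: intensity functions, von Mises phase locking, the
vector-strength/concentration inversion, and Poisson train statistics."""

import numpy as np
import pytest
from scipy import integrate

from olivesim.input_stage import (
    InputEnsembleConfig,
    SpikeTrain,
    StimulusSpec,
    am_intensity,
    am_mean_intensity,
    build_input_set,
    concentration_from_vs,
    generate_inhomogeneous_poisson,
    level_intensity,
    target_vector_strength,
    von_mises_density,
    vs_from_concentration,
)
from olivesim.metrics import vector_strength


class TestIntensityFunctions:
    @pytest.mark.parametrize("f_m, expected", [(0, 180.0), (1000, 150.0), (1200, 144.0)])
    def test_am_mean_intensity(self, f_m, expected):
        assert am_mean_intensity(f_m) == pytest.approx(expected)

    def test_am_mean_intensity_rejects_negative(self):
        with pytest.raises(ValueError):
            am_mean_intensity(-1.0)

    def test_level_intensity_sigmoid(self):
        assert level_intensity(20.0) == pytest.approx(150.0)
        assert level_intensity(-300.0) == pytest.approx(30.0, abs=1e-6)
        assert level_intensity(300.0) == pytest.approx(270.0, abs=1e-6)
        spl = np.linspace(-40, 80, 200)
        assert np.all(np.diff(level_intensity(spl)) > 0)

    def test_target_vs_closed_form_and_monotone(self):
        e = np.exp((1000.0 - 2000.0) / 500.0)
        assert target_vector_strength(1000.0) == pytest.approx(0.65 * (1 - e) / (1 + e))
        f = np.arange(50.0, 1999.0, 50.0)
        vs = np.array([target_vector_strength(x) for x in f])
        assert np.all(np.diff(vs) < 0)
        assert np.all(vs < 0.65)

    def test_target_vs_clamps_above_2khz(self):
        with pytest.warns(UserWarning):
            assert target_vector_strength(2000.0) == 0.0


class TestVonMises:
    def test_uniform_at_zero_concentration(self):
        x = np.linspace(-np.pi, np.pi, 7)
        assert von_mises_density(x, 0.0) == pytest.approx(1.0 / (2 * np.pi))

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_normalization(self, k):
        val, _ = integrate.quad(lambda x: von_mises_density(x, k), 0, 2 * np.pi)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_maximum_at_zero(self):
        x = np.linspace(-np.pi, np.pi, 101)
        p = von_mises_density(x, 3.0)
        assert np.all(von_mises_density(0.0, 3.0) >= p)

    def test_am_intensity_mean_and_uniform(self):
        # k = 0: constant at lambda1
        t = np.linspace(0, 0.01, 11)
        assert am_intensity(t, 300.0, 0.0, 150.0) == pytest.approx(150.0)
        # time average over one period equals lambda1 for any k
        val, _ = integrate.quad(
            lambda tt: am_intensity(tt, 300.0, 4.0, 150.0), 0, 1 / 300.0,
            limit=200,
        )
        assert val * 300.0 == pytest.approx(150.0, rel=1e-8)

    def test_am_intensity_peak_follows_offset(self):
        # peak where the modulation phase equals the offset (in cycles)
        f_m, offset = 100.0, 0.3
        t = np.linspace(0, 1 / f_m, 2001)
        lam = am_intensity(t, f_m, 5.0, 150.0, phase_offset=offset)
        assert t[np.argmax(lam)] * f_m == pytest.approx(offset, abs=1e-3)


class TestConcentrationInversion:
    @pytest.mark.parametrize("k", [0.0, 0.1, 1.0, 5.0, 20.0])
    def test_round_trip(self, k):
        assert concentration_from_vs(vs_from_concentration(k)) == pytest.approx(
            k, rel=1e-8, abs=1e-8
        )

    def test_against_independent_bessel_quadrature(self):
        # invert VS = 0.65 and check I1(k)/I0(k) using the integral
        # definition of the modified Bessel functions as the oracle
        k = concentration_from_vs(0.65)

        def bessel_i(n, kk):
            val, _ = integrate.quad(
                lambda x: np.exp(kk * np.cos(x)) * np.cos(n * x), -np.pi, np.pi
            )
            return val / (2 * np.pi)

        assert bessel_i(1, k) / bessel_i(0, k) == pytest.approx(0.65, abs=1e-9)

    def test_rejects_unattainable_vs(self):
        with pytest.raises(ValueError):
            concentration_from_vs(1.0)


class TestPoissonGeneration:
    def test_zero_intensity_gives_empty_train(self, rng):
        train = generate_inhomogeneous_poisson(lambda t: 0.0 * t, 10.0, 0.0, rng)
        assert len(train) == 0

    def test_homogeneous_rate_recovery(self, rng):
        train = generate_inhomogeneous_poisson(
            lambda t: np.full_like(t, 30.0), 100.0, 30.0, rng
        )
        assert abs(len(train) - 3000) < 3 * np.sqrt(3000)

    def test_envelope_violation_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_inhomogeneous_poisson(
                lambda t: np.full_like(t, 50.0), 1.0, 30.0, rng
            )

    @pytest.mark.parametrize("f_m", [150.0, 300.0, 450.0, 1000.0])
    def test_phase_locking_recovery(self, f_m):
        stim = StimulusSpec.am_monaural(f_m, duration=100.0)
        s = build_input_set(stim, InputEnsembleConfig(m_ex=1, m_inh=0), seed=7)
        vs = vector_strength(s.excitatory[0], f_m)
        assert vs == pytest.approx(target_vector_strength(f_m), abs=0.02)
        # rate within 3 SE of the programmed mean intensity
        lam = am_mean_intensity(f_m)
        rate = s.excitatory[0].rate(100.0)
        assert abs(rate - lam) < 3 * np.sqrt(lam / 100.0)


class TestBuildInputSet:
    def test_determinism(self):
        stim = StimulusSpec.am_binaural(300.0, 0.25, duration=1.0)
        a = build_input_set(stim, seed=11)
        b = build_input_set(stim, seed=11)
        assert a == b
        c = build_input_set(stim, seed=12)
        assert a != c

    def test_tone_binaural_rates(self):
        stim = StimulusSpec.tone_binaural(35.0, -10.0, duration=50.0)
        s = build_input_set(stim, seed=2)
        rate_ex = np.mean([tr.rate(50.0) for tr in s.excitatory])
        rate_inh = np.mean([tr.rate(50.0) for tr in s.inhibitory])
        lam_ex, lam_inh = level_intensity(35.0), level_intensity(-10.0)
        assert abs(rate_ex - lam_ex) < 3 * np.sqrt(lam_ex / (50.0 * 20))
        assert abs(rate_inh - lam_inh) < 3 * np.sqrt(lam_inh / (50.0 * 8))

    def test_monaural_inhibition_is_unlocked(self):
        stim = StimulusSpec.am_monaural(300.0, duration=50.0)
        s = build_input_set(stim, seed=3)
        pooled = np.concatenate([tr.times for tr in s.inhibitory])
        vs = vector_strength(SpikeTrain(np.sort(pooled)), 300.0)
        # expected resultant of N uniform phases ~ 1/sqrt(N)
        assert vs < 3.0 / np.sqrt(pooled.size)

    def test_positive_phase_diff_makes_inhibition_lead(self):
        f_m, dphi = 100.0, 0.25
        stim = StimulusSpec.am_binaural(f_m, dphi, duration=50.0)
        s = build_input_set(stim, seed=4)

        def mean_phase(trains):
            t = np.concatenate([tr.times for tr in trains])
            ph = 2 * np.pi * f_m * t
            return np.angle(np.mean(np.exp(1j * ph))) / (2 * np.pi)

        ex_phase = mean_phase(s.excitatory)
        inh_phase = mean_phase(s.inhibitory)
        assert ex_phase == pytest.approx(0.0, abs=0.02)
        # inhibition peaks a quarter cycle earlier
        lead = (ex_phase - inh_phase) % 1.0
        assert lead == pytest.approx(dphi, abs=0.02)

    def test_fiber_substreams_are_independent(self):
        stim = StimulusSpec.am_monaural(300.0, duration=100.0)
        s = build_input_set(stim, InputEnsembleConfig(m_ex=2, m_inh=0), seed=5)
        edges = np.arange(0, 100.001, 1.0)
        c0, _ = np.histogram(s.excitatory[0].times, edges)
        c1, _ = np.histogram(s.excitatory[1].times, edges)
        r = np.corrcoef(c0, c1)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(edges) - 1)

    def test_adding_fibers_preserves_existing_streams(self):
        stim = StimulusSpec.am_monaural(300.0, duration=2.0)
        small = build_input_set(stim, InputEnsembleConfig(m_ex=2, m_inh=1), seed=6)
        big = build_input_set(stim, InputEnsembleConfig(m_ex=4, m_inh=2), seed=6)
        assert small.excitatory[0] == big.excitatory[0]
        assert small.inhibitory[0] == big.inhibitory[0]

    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain([0.2, 0.1])
        with pytest.raises(ValueError):
            StimulusSpec.am_monaural(300.0, duration=-1.0)
        with pytest.raises(ValueError):
            StimulusSpec(mode="am_monaural", duration=1.0)  # missing f_m
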