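import math

import numpy as np
import pytest

import gaitpolar as gp
from gaitpolar.oscillator import TWO_PI, run_oscillator


def series_from_signal(u, fs=100.0):
    u = np.asarray(u, float)
    return gp.COPxSeries(t=np.arange(u.size) / fs, copx=u,
                         valid_mask=np.ones(u.size, bool))


def euler_reference_step(phi, alpha, alpha0, omega, u, p):
    """Independent scalar transcription of the oscillator update."""
    uhat = alpha0 + sum(alpha[i] * math.sin(phi[i]) for i in range(p.order))
    e = u - uhat
    phi_new = [phi[i] + p.dt * ((i + 1) * omega + p.k_phi * e * math.cos(phi[i]))
               for i in range(p.order)]
    omega_new = omega + p.dt * p.k_omega * e * math.cos(phi[0])
    alpha_new = [alpha[i] + p.dt * p.k_alpha * e * math.sin(phi[i])
                 for i in range(p.order)]
    alpha0_new = alpha0 + p.dt * p.k_0 * e
    return phi_new, alpha_new, alpha0_new, max(omega_new, p.omega_floor)


class TestAOStep:
    def test_zero_error_fixed_point_is_exact(self):
        p = gp.ao_profile("healthy")
        state = gp.AOState(phi=np.linspace(0.3, 2.0, 5), alpha=np.array([1.0, 0.3, 0.1, 0.05, 0.01]),
                           alpha0=0.4, omega=6.0)
        u = state.reconstruct()  # e = 0 by construction
        new = gp.ao_step(state, u, p)
        assert new.omega == state.omega
        assert new.alpha0 == state.alpha0
        np.testing.assert_array_equal(new.alpha, state.alpha)
        np.testing.assert_allclose(new.phi - state.phi,
                                   np.arange(1, 6) * state.omega * p.dt, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_euler_transcription(self, seed):
        rng = np.random.default_rng(seed)
        p = gp.ao_profile("healthy")
        state = gp.AOState(phi=rng.uniform(0, 7, 5), alpha=rng.normal(0, 1, 5),
                           alpha0=rng.normal(), omega=rng.uniform(1, 10))
        u = rng.normal()
        got = gp.ao_step(state, u, p)
        phi, alpha, alpha0, omega = euler_reference_step(
            list(state.phi), list(state.alpha), state.alpha0, state.omega, u, p)
        np.testing.assert_allclose(got.phi, phi, rtol=1e-12)
        np.testing.assert_allclose(got.alpha, alpha, rtol=1e-12)
        assert got.alpha0 == pytest.approx(alpha0, rel=1e-12)
        assert got.omega == pytest.approx(omega, rel=1e-12)

    def test_constant_input_offset_convergence(self):
        c = 2.5
        p = gp.ao_profile("healthy", input_scale=1.0)
        series = series_from_signal(np.full(1000, c))  # 10 s
        out = gp.estimate_phase(series, p)
        # the offset state absorbs the constant: reconstruction converges to c
        assert abs(out.uhat[-1] - c) < 0.01 * abs(c)
        assert abs(out.error[-1]) < 0.01 * abs(c)

    def test_non_finite_input_raises(self):
        p = gp.ao_profile("healthy")
        with pytest.raises(gp.NumericError):
            gp.ao_step(gp.AOState.initial(p), float("nan"), p)

    def test_invalid_params_rejected(self):
        with pytest.raises(gp.ValidationError):
            gp.AOParams(k_phi=0.0)
        with pytest.raises(gp.ValidationError):
            gp.AOParams(order=0)
        with pytest.raises(gp.ValidationError):
            gp.ao_profile("nonexistent")


class TestEstimatePhase:
    def test_sinusoid_frequency_recovery_nominal(self):
        t = np.arange(0, 20, 0.01)
        out = gp.estimate_phase(series_from_signal(np.sin(2 * np.pi * 1.0 * t)),
                                gp.ao_profile("healthy"))
        assert abs(out.omega_series[-1] - TWO_PI) / TWO_PI < 0.05
        assert out.converged

    def test_zero_input_keeps_initial_frequency(self):
        p = gp.ao_profile("healthy")
        out = gp.estimate_phase(series_from_signal(np.zeros(500)), p)
        np.testing.assert_allclose(out.omega_series, p.omega_init)
        # phase advances linearly at omega_init
        phi_unwrapped = np.unwrap(out.phase)
        np.testing.assert_allclose(np.diff(phi_unwrapped), p.omega_init * p.dt, rtol=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(gp.ValidationError):
            gp.estimate_phase(series_from_signal(np.zeros(100)), gp.ao_profile("healthy"))

    def test_halving_dt_changes_terminal_omega_little(self):
        f = 1.0
        t1 = np.arange(0, 20, 0.01)
        u1 = np.sin(2 * np.pi * f * t1)
        t2 = np.arange(0, 20, 0.005)
        u2 = np.sin(2 * np.pi * f * t2)
        p1 = gp.ao_profile("healthy", input_scale=1.0)
        p2 = gp.ao_profile("healthy", input_scale=1.0, dt=0.005)
        w1 = run_oscillator(u1, p1)[1][-1]
        w2 = run_oscillator(u2, p2)[1][-1]
        assert abs(w1 - w2) / w1 < 0.01

    def test_phase_in_range_and_aligned(self, clean_pipeline):
        _, _, cop, phase = clean_pipeline
        assert phase.phase.shape == cop.copx.shape
        assert np.all(phase.phase >= 0) and np.all(phase.phase < TWO_PI)


class TestCyclePhaseStats:
    def test_linear_ramp_spans_bounded_by_discretization(self):
        omega, dt = TWO_PI, 0.01
        t = np.arange(0, 10, dt)
        phase = np.mod(omega * t, TWO_PI)
        series = gp.GaitPhaseSeries(t=t, phase=phase, omega_series=np.full_like(t, omega),
                                    uhat=np.zeros_like(t), error=np.zeros_like(t))
        stats = gp.cycle_phase_stats(series, skip_initial=0)
        assert np.all(stats.spans <= TWO_PI)
        assert np.all(stats.spans >= TWO_PI - omega * dt - 1e-9)
        assert 0 <= stats.deficit <= omega * dt

    def test_too_few_wraps_raises(self):
        t = np.arange(0, 1, 0.01)
        series = gp.GaitPhaseSeries(t=t, phase=np.mod(TWO_PI * t, TWO_PI),
                                    omega_series=np.full_like(t, TWO_PI),
                                    uhat=np.zeros_like(t), error=np.zeros_like(t))
        with pytest.raises(gp.InsufficientCyclesError):
            gp.cycle_phase_stats(series)

    def test_synthetic_gait_deficit_small(self, clean_pipeline):
        _, _, _, phase = clean_pipeline
        stats = gp.cycle_phase_stats(phase)
        assert stats.deficit < 0.1
        assert stats.n_cycles >= 15

    def test_reference_phase_table_group_means(self):
        df = gp.load_reference_gait_phase()
        healthy = df[df.group == "healthy"].phase_mean
        stroke = df[df.group == "stroke"].phase_mean
        assert gp.round_half_away(healthy.mean(), 3) == 6.275
        assert gp.round_half_away(float(np.std(healthy, ddof=1)), 3) == 0.004
        assert gp.round_half_away(stroke.mean(), 3) == 6.262
        assert gp.round_half_away(float(np.std(stroke, ddof=1)), 3) == 0.009
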