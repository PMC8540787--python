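"""Constitutive-model solvers: forcing assembly, boundary conditions,
closed-form limits, and agreement with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsetf import (
    SampledSignal,
    ViscoParams,
    forcing_term,
    forward_stress,
    harmonic_transfer,
    solve_strain_periodic,
    solve_strain_release,
)
from pulsetf.errors import ContractError, ParameterError, UnitError

from conftest import fft_strain_oracle, rel_l2


class TestViscoParams:
    def test_derived_rates(self, ref_params):
        p = ref_params
        assert p.a == pytest.approx(p.E2 / p.eta)
        assert p.tau_sigma == pytest.approx(p.eta / (p.E1 + p.E2))
        assert p.E_inf < min(p.E1, p.E2)
        assert p.E_inst == p.E1

    @pytest.mark.parametrize("bad", [dict(E1=0), dict(E2=-1.0), dict(eta=0.0)])
    def test_positivity_enforced(self, bad):
        kw = dict(E1=1.0, E2=1.0, eta=1.0)
        kw.update(bad)
        with pytest.raises(ParameterError):
            ViscoParams(**kw)


class TestForcingTerm:
    def test_constant_stress_unit_parameters(self):
        # sigma_dot = 0, so F = (E1+E2)*sigma0/(E1*eta) = 2 for unit constants
        s = SampledSignal(np.ones(100), 1e-3, unit="Pa")
        F = forcing_term(s, ViscoParams(1.0, 1.0, 1.0)).F.values
        assert F == pytest.approx(np.full(100, 2.0), abs=1e-12)

    def test_zero_stress_gives_zero_forcing(self, ref_params):
        s = SampledSignal(np.zeros(50), 1e-3, unit="Pa")
        assert np.all(forcing_term(s, ref_params).F.values == 0.0)

    def test_sine_matches_analytic_derivative(self, ref_params):
        dt, T = 1e-3, 0.65
        n = int(round(T / dt))
        t = np.arange(n) * dt
        w = 2 * np.pi / T
        s = SampledSignal(np.sin(w * t), dt, unit="Pa", periodic=True)
        F = forcing_term(s, ref_params).F.values
        p = ref_params
        Fa = (p.E1 + p.E2) / (p.E1 * p.eta) * (
            np.sin(w * t) + p.eta / (p.E1 + p.E2) * w * np.cos(w * t))
        assert np.max(np.abs(F - Fa)) < 1e-4 * np.max(np.abs(Fa))

    def test_strain_unit_rejected(self, ref_params):
        s = SampledSignal(np.ones(10), 1e-3, unit="strain")
        with pytest.raises(UnitError):
            forcing_term(s, ref_params)

    def test_mmhg_converted_to_si(self, ref_params):
        v = np.ones(10)
        f_pa = forcing_term(SampledSignal(v * 133.322, 1e-3, unit="Pa"), ref_params)
        f_mm = forcing_term(SampledSignal(v, 1e-3, unit="mmHg"), ref_params)
        assert f_mm.F.values == pytest.approx(f_pa.F.values, rel=1e-12)


class TestReleaseSolver:
    def test_zero_stress_zero_strain(self, ref_params):
        s = SampledSignal(np.zeros(100), 1e-3, unit="Pa")
        assert np.all(solve_strain_release(s, ref_params).values == 0.0)

    def test_terminal_boundary_condition_exact(self, band_limited_stress, ref_params):
        # release solver on an arbitrary finite record (reuse the smooth
        # stress as a non-periodic trace)
        s = SampledSignal(band_limited_stress.values, band_limited_stress.dt, unit="Pa")
        eps = solve_strain_release(s, ref_params).values
        assert abs(eps[-1]) <= 1e-12 * np.max(np.abs(eps))

    def test_triangular_ramp_matches_rk4(self):
        """Terminal-value RK4 integration of the strain ODE is an
        independent route to the release solution."""
        params = ViscoParams(2.0, 1.0, 1.0)
        dt, T = 1e-3, 2.0
        n = int(round(T / dt)) + 1
        t = np.arange(n) * dt
        sigma = 1.0 - np.abs(1.0 - t)
        s = SampledSignal(sigma, dt, unit="Pa")
        eps = solve_strain_release(s, params).values

        a = params.a
        c = (params.E1 + params.E2) / (params.E1 * params.eta)
        tau = params.eta / (params.E1 + params.E2)

        def F(tt):
            sg = np.interp(tt, t, sigma)
            sgd = 1.0 if tt < 1.0 else -1.0
            return c * (sg + tau * sgd)

        # integrate y(s) = eps(T - s) forward from y(0) = 0 with RK4
        h = dt / 2
        y, ys = 0.0, [0.0]
        f = lambda s_, y_: a * y_ - F(T - s_)
        for i in range(int(round(T / h))):
            s_ = i * h
            k1 = f(s_, y)
            k2 = f(s_ + h / 2, y + h / 2 * k1)
            k3 = f(s_ + h / 2, y + h / 2 * k2)
            k4 = f(s_ + h, y + h * k3)
            y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ys.append(y)
        oracle = np.array(ys)[::-1][::2]
        assert rel_l2(eps, oracle) < 1e-4

    def test_periodic_input_rejected(self, band_limited_stress, ref_params):
        with pytest.raises(ContractError):
            solve_strain_release(band_limited_stress, ref_params)

    def test_large_rate_does_not_produce_nan(self):
        """a*T far beyond exp overflow must degrade gracefully (no NaN)."""
        params = ViscoParams(E1=1e6, E2=80e6, eta=1e2)  # a = 8e5 1/s
        dt = 1e-3
        n = 2001
        t = np.arange(n) * dt
        s = SampledSignal(1.0 - np.abs(1.0 - t), dt, unit="Pa")
        eps = solve_strain_release(s, params).values
        assert not np.any(np.isnan(eps))


class TestPeriodicSolver:
    def test_constant_forcing_fixed_point(self, ref_params):
        # constant sigma => constant F = F0, and eps = F0/a solves the ODE
        s = SampledSignal(np.full(100, 1e3), 1e-3, unit="Pa", periodic=True)
        F0 = forcing_term(s, ref_params).F.values[0]
        eps = solve_strain_periodic(s, ref_params).values
        assert eps == pytest.approx(np.full(100, F0 / ref_params.a), rel=1e-10)

    def test_cosine_matches_single_harmonic_transfer(self, ref_params):
        dt, T = 1e-3, 0.65
        n = int(round(T / dt))
        t = np.arange(n) * dt
        w = 2 * np.pi / T
        s = SampledSignal(2e3 * np.cos(w * t), dt, unit="Pa", periodic=True)
        eps = solve_strain_periodic(s, ref_params).values
        H = harmonic_transfer(ref_params, w)
        oracle = np.real(2e3 * H * np.exp(1j * w * t))
        assert rel_l2(eps, oracle) < 1e-3

    def test_band_limited_matches_fft_oracle(self, band_limited_stress, ref_params):
        eps = solve_strain_periodic(band_limited_stress, ref_params).values
        oracle = fft_strain_oracle(band_limited_stress, ref_params)
        assert rel_l2(eps, oracle) < 1e-3

    def test_periodic_boundary_condition_exact(self, band_limited_stress, ref_params):
        ext = solve_strain_periodic(band_limited_stress, ref_params,
                                    include_wrap=True).values
        assert abs(ext[-1] - ext[0]) <= 1e-10 * np.max(np.abs(ext))

    def test_non_periodic_input_rejected(self, ref_params):
        s = SampledSignal(np.zeros(10), 1e-3, unit="Pa")
        with pytest.raises(ContractError):
            solve_strain_periodic(s, ref_params)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5))
    def test_linearity(self, band_limited_stress, ref_params, alpha, beta):
        s1 = band_limited_stress
        v2 = np.roll(s1.values, 100) ** 1  # an independent-phase companion
        s2 = s1.with_values(v2)
        combo = s1.with_values(alpha * s1.values + beta * v2)
        lhs = solve_strain_periodic(combo, ref_params).values
        rhs = (alpha * solve_strain_periodic(s1, ref_params).values
               + beta * solve_strain_periodic(s2, ref_params).values)
        scale = np.max(np.abs(rhs)) or 1.0
        assert np.max(np.abs(lhs - rhs)) <= 1e-10 * max(scale, 1e-30)


class TestForwardStress:
    def test_elastic_limit_eta_to_zero(self, ref_params):
        """With a negligible dashpot the chain is two springs in series:
        sigma = E_inf * eps pointwise."""
        p = ViscoParams(ref_params.E1, ref_params.E2, 1e-9 * ref_params.E2)
        dt, T = 1e-3, 0.65
        n = int(round(T / dt))
        t = np.arange(n) * dt
        eps = SampledSignal(0.01 * np.sin(2 * np.pi * t / T) + 0.02, dt,
                            unit="strain", periodic=True)
        sigma = forward_stress(eps, p).values
        expected = p.E_inf * eps.values
        assert np.max(np.abs(sigma - expected)) < 1e-6 * np.max(np.abs(expected))

    def test_step_strain_relaxation_closed_form(self, ref_params):
        """Stress relaxes from E1*eps0 to E_inf*eps0 with time constant
        eta/(E1+E2) — the standard-linear-solid relaxation function."""
        p = ref_params
        eps0, dt, n = 0.01, 1e-3, 2000
        t = np.arange(n) * dt
        sigma = forward_stress(SampledSignal(np.full(n, eps0), dt, unit="strain"), p).values
        closed = p.E_inf * eps0 + (p.E1 - p.E_inf) * eps0 * np.exp(-t / p.tau_sigma)
        assert np.max(np.abs(sigma - closed)) < 1e-3 * p.E1 * eps0
        assert sigma[0] == pytest.approx(p.E1 * eps0, rel=1e-12)

    def test_periodic_round_trip(self, band_limited_stress, ref_params):
        eps = solve_strain_periodic(band_limited_stress, ref_params)
        sigma = forward_stress(eps, ref_params)
        eps2 = solve_strain_periodic(sigma, ref_params).values
        assert rel_l2(eps2, eps.values) < 5e-3

    def test_release_round_trip(self, ref_params):
        """Inverting the forward response of a triangular strain ramp with
        the release solver recovers the ramp (its strain ends at zero)."""
        dt, n = 1e-3, 2001
        t = np.arange(n) * dt
        ramp = 0.2 * (1.0 - np.abs(1.0 - t))
        eps = SampledSignal(ramp, dt, unit="strain")
        sigma = forward_stress(eps, ref_params)
        eps2 = solve_strain_release(sigma, ref_params).values
        assert rel_l2(eps2, ramp) < 1e-3

    def test_pressure_unit_rejected(self, ref_params):
        with pytest.raises(UnitError):
            forward_stress(SampledSignal(np.ones(10), 1e-3, unit="Pa"), ref_params)


class TestHarmonicTransfer:
    def test_static_and_instantaneous_limits(self, ref_params):
        p = ref_params
        assert harmonic_transfer(p, 0.0) == pytest.approx(1.0 / p.E_inf)
        assert harmonic_transfer(p, 1e12) == pytest.approx(1.0 / p.E1, rel=1e-6)

    def test_pole_at_strain_relaxation_rate(self, ref_params):
        # a = E2/eta = 71.32/39.94 ~ 1.7857 1/s for the reference constants
        assert ref_params.a == pytest.approx(71.32 / 39.94, rel=1e-12)
        # |H| peaks as omega -> pole scale; verify the denominator root
        w = ref_params.a
        denom = ref_params.a + 1j * w
        assert abs(denom) == pytest.approx(np.sqrt(2) * ref_params.a)

    def test_negative_frequency_rejected(self, ref_params):
        with pytest.raises(ContractError):
            harmonic_transfer(ref_params, -1.0)


class TestPhaseLag:
    def test_lag_increases_with_eta_at_low_frequency(self, ref_params):
        """Below the corner frequency sqrt(E2*(E1+E2))/ (omega*eta) the
        strain's phase lag behind a sinusoidal stress grows with eta.
        (The closed form arctan(w*eta/E2) - arctan(w*eta/(E1+E2)) peaks at
        w*eta = sqrt(E2*(E1+E2)) and decreases beyond it.)"""
        w = 0.5  # rad/s, low enough for all etas below
        lags = []
        for eta in (10e6, 20e6, 40e6, 80e6):
            p = ViscoParams(ref_params.E1, ref_params.E2, eta)
            lags.append(-np.angle(harmonic_transfer(p, w)))
        assert np.all(np.diff(lags) > 0)

    def test_lag_vanishes_as_eta_to_zero(self, ref_params):
        p = ViscoParams(ref_params.E1, ref_params.E2, 1e-3)
        assert abs(np.angle(harmonic_transfer(p, 10.0))) < 1e-6
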