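"""Kinetic-model layer: conductance, closed-form current, ODE oracle,
derived quantities, peak timing, reversal potential."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipscfit.models import (
    ACSF_SOLUTION_MM,
    PIPETTE_SOLUTION_MM,
    BiexpParams,
    ClampContext,
    ExcludedParameterError,
    GephyrinParams,
    ParameterDomainError,
    SingularParameterError,
    TimeGrid,
    biexp_peak_time,
    chloride_concentration,
    eval_biexp_current,
    eval_current_analytic,
    eval_g,
    integrate_ode,
    nernst_potential,
    peak_time,
    steady_states,
)

from conftest import random_valid_params


class TestConductance:
    def test_zero_at_onset_and_decays_to_zero(self):
        p = GephyrinParams(w=2.0, tau_r=0.2, tau_d=8.0, t0=3.0)
        t = np.array([0.0, 3.0, 500.0])
        g = eval_g(p, t)
        assert g[0] == 0.0  # before onset
        assert g[1] == 0.0  # exponentials cancel at t' = 0
        assert g[2] == pytest.approx(0.0, abs=1e-12)

    def test_scalar_substitution(self):
        # w=1, tau_r=1, tau_d=2 at t' = 2 ln 2: direct substitution oracle
        p = GephyrinParams(w=1.0, tau_r=1.0, tau_d=2.0)
        tp = 2.0 * math.log(2.0)
        expected = math.exp(-tp / 2.0) - math.exp(-tp / 1.0)
        assert eval_g(p, np.array([tp]))[0] == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.25, rel=1e-12)

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterDomainError):
            GephyrinParams(tau_r=5.0, tau_d=3.0)
        with pytest.raises(ParameterDomainError):
            GephyrinParams(w=-1.0)
        with pytest.raises(ParameterDomainError):
            GephyrinParams(t0=-0.5)


class TestSteadyStates:
    def test_nlg2_hand_solution(self):
        # dNLG2/dt = 0 with Nlmax=GEPH, Nhalf=GEPH/2: GEPH=2, phi=1 -> NLG2=1
        der = steady_states(GephyrinParams(geph=2.0, phi=1.0))
        assert der.nlg2_ss == pytest.approx(1.0)
        assert der.nlmax == 2.0
        assert der.nhalf == 1.0

    def test_phi_at_two_is_excluded(self):
        with pytest.raises(ExcludedParameterError):
            steady_states(GephyrinParams(phi=1.9999999999 + 1e-9))

    def test_unit_amplitude_factor(self):
        # all unit parameters: I_FACT = (2-1)/2 = 0.5
        der = steady_states(GephyrinParams(
            w=1, tau_r=0.2, tau_d=8, beta=1, alpha_f=1, alpha_b=1,
            geph=1, phi=1, h=1, h1=1, c1=1))
        assert der.i_fact == pytest.approx(0.5)

    def test_ry_steady_state(self):
        der = steady_states(GephyrinParams(h=3.0, h1=1.5, geph=2.0))
        assert der.ry_ss == pytest.approx(4.0)


class TestAnalyticCurrent:
    def test_zero_at_onset_and_infinity(self, ctx):
        p = GephyrinParams(t0=2.0)
        t = np.array([0.0, 2.0, 2000.0])
        cur = eval_current_analytic(p, ctx, t)
        assert cur[0] == 0.0
        assert cur[1] == pytest.approx(0.0, abs=1e-12)
        assert cur[2] == pytest.approx(0.0, abs=1e-12)

    def test_inward_sign_for_hyperpolarized_holding(self, ctx):
        # v < erev: driving force negative, current inward (negative)
        p = GephyrinParams()
        t = np.linspace(0.1, 40.0, 200)
        cur = eval_current_analytic(p, ctx, t)
        assert np.all(cur <= 1e-12)
        assert cur.min() < -1.0

    def test_geph_scaling_is_quadratic(self, ctx):
        p = GephyrinParams()
        t = np.linspace(0.0, 60.0, 500)
        base = eval_current_analytic(p, ctx, t)
        doubled = eval_current_analytic(replace(p, geph=2.0), ctx, t)
        np.testing.assert_array_equal(doubled, 4.0 * base)

    @pytest.mark.parametrize("field", ["w", "beta", "alpha_f", "c1", "h"])
    def test_linear_scaling_fields(self, ctx, field):
        p = GephyrinParams()
        t = np.linspace(0.0, 60.0, 500)
        base = eval_current_analytic(p, ctx, t)
        scaled = eval_current_analytic(
            replace(p, **{field: 3.0 * getattr(p, field)}), ctx, t)
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-14)

    def test_inverse_in_h1_and_hyperbolic_in_phi(self, ctx):
        p = GephyrinParams()
        t = np.linspace(0.0, 60.0, 200)
        base = eval_current_analytic(p, ctx, t)
        halved_h1 = eval_current_analytic(replace(p, h1=0.5), ctx, t)
        np.testing.assert_allclose(halved_h1, 2.0 * base, rtol=1e-14)
        for phi in (0.5, 1.5):
            factor = ((2.0 - phi) / (2.0 * phi)) / ((2.0 - 1.0) / 2.0)
            scaled = eval_current_analytic(replace(p, phi=phi), ctx, t)
            np.testing.assert_allclose(scaled, factor * base, rtol=1e-13)

    def test_singularity_guard(self, ctx):
        p = GephyrinParams(alpha_b=1.0 / 8.0 + 1e-9, tau_d=8.0)
        with pytest.raises(SingularParameterError):
            eval_current_analytic(p, ctx, np.linspace(0, 10, 10))

    def test_matches_ode_oracle(self, ctx):
        rng = np.random.default_rng(42)
        grid = TimeGrid(dt=0.05, n=1201)
        for _ in range(10):
            p = random_valid_params(rng)
            ana = eval_current_analytic(p, ctx, grid.times())
            ode = integrate_ode(p, ctx, grid)
            rel = np.max(np.abs(ana - ode)) / np.max(np.abs(ana))
            assert rel < 1e-6

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.2, 3.0), scale=st.floats(0.3, 3.0),
        geph=st.floats(0.5, 2.0),
    )
    def test_identifiability_of_amplitude_combination(self, h, scale, geph):
        """Two parameter sets sharing (I_FACT, alpha_b, tau_r, tau_d, t0)
        produce bit-identical currents: the amplitude factor lumps every
        other parameter."""
        ctx = ClampContext()
        p1 = GephyrinParams(h=h, h1=1.0, geph=geph)
        # trade h against h1 and geph^2 against c1, keeping I_FACT fixed
        p2 = replace(p1, h=h * scale, h1=scale)
        p3 = replace(p1, geph=geph * 2.0, c1=p1.c1 / 4.0)
        t = np.linspace(0.0, 50.0, 400)
        i1 = eval_current_analytic(p1, ctx, t)
        sa = steady_states(p1).i_fact
        assert steady_states(p2).i_fact == pytest.approx(sa, rel=1e-12)
        np.testing.assert_allclose(eval_current_analytic(p2, ctx, t), i1,
                                   rtol=1e-12)
        np.testing.assert_allclose(eval_current_analytic(p3, ctx, t), i1,
                                   rtol=1e-12)


class TestOdeIntegration:
    def test_zero_drive_gives_zero_current(self, ctx):
        # w > 0 required by the domain; drive suppressed via tiny w instead
        p = GephyrinParams(w=1e-300)
        grid = TimeGrid(dt=0.1, n=201)
        cur = integrate_ode(p, ctx, grid)
        assert np.max(np.abs(cur)) < 1e-250

    def test_steady_states_are_fixed_points(self, ctx):
        from scipy.integrate import solve_ivp

        p = GephyrinParams(geph=1.7, phi=0.8, h=2.0, h1=0.5)
        der = steady_states(p)

        def rhs(_t, y):
            nlg2, ry = y
            return [der.nlmax / (1.0 + der.nhalf / nlg2) - p.phi * nlg2,
                    p.h * p.geph - p.h1 * ry]

        sol = solve_ivp(rhs, (0, 100), [der.nlg2_ss, der.ry_ss],
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[:, -1], [der.nlg2_ss, der.ry_ss],
                                   rtol=1e-8)


class TestBiexp:
    def test_zero_at_onset(self, ctx):
        p = BiexpParams(t_start=1.0)
        cur = eval_biexp_current(p, ctx, np.array([0.0, 1.0]))
        assert cur[0] == 0.0
        assert cur[1] == pytest.approx(0.0, abs=1e-12)

    def test_peak_conductance_equals_weight(self, ctx):
        p = BiexpParams(tau1=1.6, tau2=7.7, t_start=0.2, weight=1.2e-3)
        t = np.arange(0.0, 60.0, 1e-3)
        cur = eval_biexp_current(p, ctx, t)
        g = cur / ctx.driving_force
        assert g.max() == pytest.approx(p.weight, rel=1e-6)
        # peak position matches the analytic formula
        tstar = biexp_peak_time(1.6, 7.7)
        assert t[np.argmax(g)] - p.t_start == pytest.approx(tstar, abs=2e-3)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ParameterDomainError):
            BiexpParams(tau1=3.0, tau2=2.0)


class TestPeakTime:
    def test_invariant_to_amplitude(self):
        p = GephyrinParams()
        q = replace(p, c1=37.0, w=2.5, geph=1.7)
        assert peak_time(p) == pytest.approx(peak_time(q), rel=1e-12)

    def test_matches_dense_grid_argmax(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = replace(random_valid_params(rng), t0=0.0)
            t = np.arange(0.0, 80.0, 1e-3)
            cur = np.abs(eval_current_analytic(p, ClampContext(), t))
            assert peak_time(p) == pytest.approx(t[np.argmax(cur)], abs=2e-3)

    def test_monotone_in_rise_constant(self):
        times = [peak_time(GephyrinParams(tau_r=tr, tau_d=8.0, alpha_b=1.0))
                 for tr in np.linspace(0.05, 0.5, 8)]
        assert np.all(np.diff(times) > 0.0)


class TestReversalPotential:
    def test_chloride_reversal_from_printed_solutions(self):
        cl_in = chloride_concentration(PIPETTE_SOLUTION_MM)
        cl_out = chloride_concentration(ACSF_SOLUTION_MM)
        assert cl_in == pytest.approx(72.0)
        assert cl_out == pytest.approx(132.5)
        e_cl = nernst_potential(cl_out, cl_in, temperature_c=32.0, charge=-1)
        assert e_cl == pytest.approx(-16.0, abs=1.0)

    def test_sign_conventions(self):
        # cation with higher outside concentration reverses positive
        assert nernst_potential(140.0, 10.0, charge=1) > 0.0
        with pytest.raises(ValueError):
            nernst_potential(-1.0, 10.0)
        with pytest.raises(ValueError):
            nernst_potential(10.0, 10.0, charge=0)


class TestDomainTypes:
    def test_time_grid_validation(self):
        with pytest.raises(ParameterDomainError):
            TimeGrid(dt=0.0, n=10)
        with pytest.raises(ParameterDomainError):
            TimeGrid(dt=0.1, n=1)
        g = TimeGrid(dt=0.5, n=4, origin=1.0)
        np.testing.assert_allclose(g.times(), [1.0, 1.5, 2.0, 2.5])

    def test_clamp_context_rejects_zero_driving_force(self):
        with pytest.raises(ParameterDomainError):
            ClampContext(v=-16.0, erev=-16.0)
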