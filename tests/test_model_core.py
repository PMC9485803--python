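"""Dose-response functions, system right-hand side and equilibrium algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from iigidyn.model_core import (MGDL_PER_MM, HysteresisAnchor,
                                InvalidArgumentError, ConfigurationError,
                                ModelParameters, SystemState, Variant,
                                c1_adjustment, glucagon_dose_response,
                                hill_response, insulin_dose_response,
                                mM_to_mgdl, mgdl_to_mM, rhs,
                                solve_equilibrium)


class TestHillResponse:
    @pytest.mark.parametrize("G,h,K,expected", [
        (17.0, 1.0, 17.0, 0.75),    # half-max glucose: 1.5/2
        (17.0, 2.7, 17.0, 0.75),    # half-max is h-independent
        (0.0, 2.0, 17.0, 0.0),
        (8.5, 1.0, 17.0, 0.5),      # 1.5 * 8.5/25.5
    ])
    def test_reference_points(self, G, h, K, expected):
        assert hill_response(G, h, K) == pytest.approx(expected, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            hill_response(-1.0, 2.0)
        with pytest.raises(InvalidArgumentError):
            hill_response(5.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            hill_response(5.0, 2.0, K=-17.0)

    @given(G=st.floats(0, 100), h=st.floats(0.5, 4), K=st.floats(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, G, h, K):
        v = hill_response(G, h, K)
        assert 0 <= v < 1.5
        assert hill_response(G + 1.0, h, K) >= v


class TestC1Adjustment:
    def test_equal_coefficients_reduce_to_prefactor(self):
        assert c1_adjustment(1.7, 1.7, 17.0, 12.0) == pytest.approx(1.5)

    @given(h1=st.floats(0.5, 4), h2=st.floats(0.5, 4),
           G=st.floats(4, 20), K=st.floats(10, 25))
    @settings(max_examples=100, deadline=None)
    def test_branch_continuity_at_anchor(self, h1, h2, G, K):
        c1 = c1_adjustment(h1, h2, K, G)
        rising = hill_response(G, h1, K)
        falling = hill_response(G, h2, K, psi_scale=c1)
        assert falling == pytest.approx(rising, rel=1e-12)

    def test_matches_numeric_branch_equality_root(self):
        h1, h2, K, G = 1.3, 2.0, 17.0, 12.0
        r2 = (G / K) ** h2
        target = hill_response(G, h1, K)
        root = brentq(lambda c: c * r2 / (1 + r2) - target, 1e-6, 100.0)
        assert c1_adjustment(h1, h2, K, G) == pytest.approx(root, rel=1e-10)


class TestInsulinDoseResponse:
    def setup_method(self):
        self.anchor = HysteresisAnchor(G_hyst=12.0, t_hyst=60.0)
        self.m2 = ModelParameters(h1=1.3, h2=2.0,
                                  variant=Variant.MODEL2_HYSTERESIS)

    def test_model1_is_plain_hill(self):
        p = ModelParameters(h=1.9)
        for t in (0.0, 50.0, 200.0):
            assert insulin_dose_response(8.0, t, p) == \
                pytest.approx(hill_response(8.0, 1.9))

    def test_rising_branch_uses_h1(self):
        assert insulin_dose_response(8.0, 10.0, self.m2, self.anchor) == \
            pytest.approx(hill_response(8.0, 1.3))

    def test_missing_anchor_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            insulin_dose_response(8.0, 10.0, self.m2, None)

    def test_falling_branch_below_rising_below_anchor(self):
        # steeper falling curve lies below the rising one for G < G_hyst
        for g in np.linspace(4.0, 11.5, 20):
            rise = insulin_dose_response(g, 10.0, self.m2, self.anchor)
            fall = insulin_dose_response(g, 100.0, self.m2, self.anchor)
            assert fall < rise

    @given(h=st.floats(0.5, 4), G=st.floats(0.1, 30),
           t=st.floats(0, 240))
    @settings(max_examples=100, deadline=None)
    def test_degenerate_hysteresis_equals_hill(self, h, G, t):
        m1 = ModelParameters(h=h)
        m2 = ModelParameters(h1=h, h2=h, variant=Variant.MODEL2_HYSTERESIS)
        anchor = HysteresisAnchor(G_hyst=12.0, t_hyst=60.0)
        assert insulin_dose_response(G, t, m2, anchor) == \
            insulin_dose_response(G, t, m1, anchor)


class TestGlucagonDoseResponse:
    anchor = HysteresisAnchor(G_hyst=10.0, t_hyst=60.0)

    def test_zero_glucose_rising_is_one(self):
        assert glucagon_dose_response(0.0, 0.0, 0.26, 0.5, self.anchor) == 1.0

    def test_rising_branch_value(self):
        assert glucagon_dose_response(5.0, 0.0, 0.26, 0.5, self.anchor) == \
            pytest.approx(math.exp(-1.3), rel=1e-12)

    def test_switch_point_value_as_printed(self):
        # at (t_hyst, G_hyst) the falling branch is exp(-k2 G) + exp(-k1 G):
        # the printed yshift, not a continuity-corrected variant
        k1, k2 = 0.26, 0.5
        v = glucagon_dose_response(10.0, 60.0, k1, k2, self.anchor)
        assert v == pytest.approx(math.exp(-5.0) + math.exp(-2.6), rel=1e-12)
        rising_at_switch = glucagon_dose_response(10.0, 59.999, k1, k2,
                                                  self.anchor)
        assert v - rising_at_switch == pytest.approx(math.exp(-k2 * 10.0),
                                                     rel=1e-9)

    def test_continuity_corrected_mode_is_continuous(self):
        v_fall = glucagon_dose_response(10.0, 60.0, 0.26, 0.5, self.anchor,
                                        continuity_corrected=True)
        v_rise = glucagon_dose_response(10.0, 0.0, 0.26, 0.5, self.anchor)
        assert v_fall == pytest.approx(v_rise, rel=1e-12)

    @given(G=st.floats(0, 30), k1=st.floats(0.01, 1), k2=st.floats(0.01, 1),
           t=st.floats(0, 240))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, G, k1, k2, t):
        v = glucagon_dose_response(G, t, k1, k2, self.anchor)
        assert v > 0
        if t < self.anchor.t_hyst:
            assert v <= 1.0
        assert glucagon_dose_response(G + 0.5, t, k1, k2, self.anchor) < v


class TestParameterValidation:
    def test_variant_field_consistency(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(h=None)
        with pytest.raises(ConfigurationError):
            ModelParameters(h=1.5, h1=1.2, h2=2.0)
        with pytest.raises(ConfigurationError):
            ModelParameters(h1=1.2, h2=None, variant=Variant.MODEL2_HYSTERESIS)

    def test_positivity(self):
        with pytest.raises(InvalidArgumentError):
            ModelParameters(h=1.5, k1=-0.1)
        with pytest.raises(InvalidArgumentError):
            ModelParameters(h=1.5, tau=-1.0)

    def test_fixed_defaults(self):
        p = ModelParameters(h=1.5)
        assert (p.SG, p.n1, p.n2, p.K, p.psi_scale, p.V) == \
            (0.014, 0.14, 0.08, 17.0, 1.5, 1.35)


class TestRhs:
    def test_uncoupled_decay(self):
        p = ModelParameters(a1=1e-300, a2=1e-300, gamma1=1e-300,
                            gamma2=1e-300, h=1.5)
        s = SystemState(t=5.0, G=100.0, I=8.0, A=9.0)
        dG, dI, dA = rhs(s, 5.5, 5.5, 0.0, p)
        assert dG == pytest.approx(-p.SG * 100.0)
        assert dI == pytest.approx(-p.n1 * 8.0)
        assert dA == pytest.approx(-p.n2 * 9.0)

    def test_equilibrium_is_stationary(self, cs_params):
        I0, A0, a2 = solve_equilibrium(cs_params, 5.5)
        p = cs_params.with_updates(a2=a2)
        s = SystemState(t=0.0, G=5.5 * MGDL_PER_MM, I=I0, A=A0)
        derivs = rhs(s, 5.5, 5.5, 0.0, p)
        assert np.allclose(derivs, 0.0, atol=1e-10)

    def test_matches_finite_difference_of_trajectory(self, cs_params,
                                                     cs_schedule, cs_initial):
        from iigidyn.simulator import simulate
        from iigidyn.infusion import build_infusion_rate, delayed_rate
        from iigidyn.model_core import RISING_ONLY_ANCHOR
        traj = simulate(cs_params, cs_schedule, RISING_ONLY_ANCHOR,
                        cs_initial, method="rk4", dt=0.05)
        rate = delayed_rate(build_infusion_rate(cs_schedule), cs_params.tau)
        eps = 1e-4
        for t in (40.0, 100.0, 200.0):
            y = traj.eval_internal(t)[:, 0]
            fd = (traj.eval_internal(t + eps)[:, 0]
                  - traj.eval_internal(t - eps)[:, 0]) / (2 * eps)
            gd1 = traj.glucose_mM(t - cs_params.tau1)[0]
            state = SystemState(t=t, G=y[0], I=y[1], A=y[2])
            ana = rhs(state, gd1, y[0] / MGDL_PER_MM, float(rate(t)),
                      cs_params, RISING_ONLY_ANCHOR)
            assert np.allclose(fd, ana, rtol=1e-5, atol=1e-7)


class TestSolveEquilibrium:
    def test_vanishing_insulin_secretion_limit(self):
        p = ModelParameters(gamma1=1e-12, h=1.9)
        I0, A0, a2 = solve_equilibrium(p, 5.0)
        assert I0 == pytest.approx(0.0, abs=1e-10)
        g0_mgdl = 5.0 * MGDL_PER_MM
        assert a2 == pytest.approx(p.SG * g0_mgdl / A0, rel=1e-6)

    def test_forced_levels_reference_value(self):
        # I0 = 5 (10 pM), A0 = 10 pM at G0 = 90 mg/dL with a1 = 5e-4:
        # a2 = (0.014 + 0.0025) * 90 / 10
        g0_mM = 90.0 / MGDL_PER_MM
        psi0 = hill_response(g0_mM, 1.9)
        p = ModelParameters(a1=5e-4, gamma1=5 * 0.14 / psi0,
                            gamma2=10 * 0.08 / math.exp(-0.26 * g0_mM),
                            k1=0.26, h=1.9)
        I0, A0, a2 = solve_equilibrium(p, g0_mM)
        assert I0 == pytest.approx(5.0, rel=1e-12)
        assert A0 == pytest.approx(10.0, rel=1e-12)
        assert a2 == pytest.approx((0.014 + 5e-4 * 5) * 90.0 / 10.0,
                                   rel=1e-12)

    def test_plugging_back_into_rhs_gives_zero(self, cs_params):
        I0, A0, a2 = solve_equilibrium(cs_params, 5.5)
        p = cs_params.with_updates(a2=a2)
        s = SystemState(t=0.0, G=mM_to_mgdl(5.5), I=I0, A=A0)
        assert np.allclose(rhs(s, 5.5, 5.5, 0.0, p), 0.0, atol=1e-10)


def test_unit_round_trip_is_identity():
    g = np.array([0.1, 5.5, 10.0, 30.0])
    assert np.allclose(mgdl_to_mM(mM_to_mgdl(g)), g, rtol=1e-12)
    assert np.allclose(mM_to_mgdl(mgdl_to_mM(g * 18.0)), g * 18.0,
                       rtol=1e-12)
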