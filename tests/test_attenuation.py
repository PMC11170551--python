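"""Attenuation-factor models and their multiplicative composition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exqnmr.attenuation import (
    AttenuationBreakdown,
    ConvectionParams,
    IterationElement,
    PFGPairParams,
    RelaxationParams,
    SelectivePulseParams,
    convection_factor,
    convection_series,
    diffusion_factor,
    element_factor,
    jmod_centerband,
    jmod_centerband_exact,
    relax_free,
    relax_selective,
    total_attenuation,
)

PFG = PFGPairParams(delta=1e-3, g=0.208, Delta=0.01, Delta_prime=0.01)


class TestRelaxation:
    @pytest.mark.parametrize(
        "t, T, expected",
        [
            (0.0, 1.0, 1.0),
            (1.0, 1.0, math.exp(-1.0)),
            (0.5, 2.0, math.exp(-0.25)),
        ],
    )
    def test_free_relaxation_closed_form(self, t, T, expected):
        assert relax_free(t, T) == pytest.approx(expected, rel=1e-15)

    def test_seven_t1_recovery_exceeds_99_9_percent(self):
        """A 7*T1 recovery delay leaves less than 0.1% unrecovered."""
        remaining = relax_free(7 * 1.3, 1.3)
        assert 1.0 - remaining >= 0.999

    @pytest.mark.parametrize("bad_T", [0.0, -1.0])
    def test_nonpositive_time_constant_rejected(self, bad_T):
        with pytest.raises(ValueError):
            relax_free(1.0, bad_T)

    def test_selective_pulse_zero_duration_identity(self):
        p = SelectivePulseParams(duration=0.0, alpha=1.7)
        assert relax_selective(p, RelaxationParams(2.0, 1.0)) == 1.0

    def test_selective_pulse_equal_time_constants_reduce_to_free(self):
        p = SelectivePulseParams(duration=0.03, alpha=1.3, t1_weight=0.7, t2_weight=0.3)
        r = RelaxationParams(T1=0.8, T2=0.8)
        assert relax_selective(p, r) == pytest.approx(relax_free(1.3 * 0.03, 0.8))

    def test_selective_pulse_biexponential_value(self):
        # exp(-0.02 * (0.5/2 + 0.5/1)) = exp(-0.015)
        p = SelectivePulseParams(duration=0.02, alpha=1.0)
        r = RelaxationParams(T1=2.0, T2=1.0)
        assert relax_selective(p, r) == pytest.approx(math.exp(-0.015), rel=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SelectivePulseParams(duration=0.01, t1_weight=0.7, t2_weight=0.7)

    def test_unphysical_t2_warns(self):
        with pytest.warns(UserWarning, match="physical bound"):
            RelaxationParams(T1=1.0, T2=3.0)


class TestDiffusionConvection:
    def test_stejskal_tanner_value(self):
        # b = (gamma*delta*g)^2 * Delta' with the 20.8 G/cm gradient pair
        assert diffusion_factor(2.3e-9, PFG) == pytest.approx(
            math.exp(-0.07120), rel=1e-3
        )

    @pytest.mark.parametrize("D", [0.0, 2.3e-9])
    def test_zero_gradient_or_diffusion_is_identity(self, D):
        nog = PFGPairParams(delta=1e-3, g=0.0, Delta=0.01, Delta_prime=0.01)
        assert diffusion_factor(0.0, PFG) == 1.0
        assert diffusion_factor(D, nog) == 1.0

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError):
            diffusion_factor(-1e-9, PFG)

    def test_diffusion_even_in_polarity(self):
        flipped = PFGPairParams(
            delta=1e-3, g=0.208, Delta=0.01, Delta_prime=0.01, polarity=-1
        )
        assert diffusion_factor(2.3e-9, PFG) == diffusion_factor(2.3e-9, flipped)

    def test_convection_identity_cases(self):
        assert convection_factor(ConvectionParams(0.0), PFG) == 1.0
        nog = PFGPairParams(delta=1e-3, g=0.0, Delta=0.01, Delta_prime=0.01)
        assert convection_factor(ConvectionParams(1e-3), nog) == 1.0

    def test_convection_cosine_argument(self):
        # choose v_max so gamma*delta*g*v_max*Delta = pi/3 -> cos = 1/2
        v = (math.pi / 3) / (PFG.gamma * PFG.delta * PFG.g * PFG.Delta)
        assert convection_factor(ConvectionParams(v), PFG) == pytest.approx(0.5)

    def test_convection_even_in_gradient_sign(self):
        neg = PFGPairParams(
            delta=1e-3, g=-0.208, Delta=0.01, Delta_prime=0.01
        )
        c = ConvectionParams(5e-4)
        assert convection_factor(c, PFG) == pytest.approx(convection_factor(c, neg))

    @pytest.mark.parametrize("n_even", [2, 4, 6])
    def test_even_iterations_fully_compensated(self, n_even):
        assert convection_series(ConvectionParams(2e-3), PFG, n_even) == 1.0

    @pytest.mark.parametrize("n_odd", [1, 3, 5])
    def test_odd_iterations_single_residual(self, n_odd):
        c = ConvectionParams(2e-3)
        assert convection_series(c, PFG, n_odd) == convection_factor(c, PFG)

    def test_invalid_iteration_count(self):
        with pytest.raises(ValueError):
            convection_series(ConvectionParams(0.0), PFG, 0)


class TestElementComposition:
    RELAX = RelaxationParams(T1=2.0, T2=1.0)

    def test_empty_element_is_identity(self):
        out = element_factor(IterationElement(), self.RELAX)
        assert out.total == 1.0

    def test_single_delay_equals_free_relaxation(self):
        e = IterationElement(free_delays=[(0.05, "transverse")])
        out = element_factor(e, self.RELAX)
        assert out.total == pytest.approx(relax_free(0.05, 1.0), rel=1e-15)

    def test_delay_plus_pfg_multiplies_factors(self):
        e = IterationElement(free_delays=[(0.05, "longitudinal")], pfg_pairs=[PFG])
        out = element_factor(e, self.RELAX, D=2.3e-9)
        expected = relax_free(0.05, 2.0) * diffusion_factor(2.3e-9, PFG)
        assert out.total == pytest.approx(expected, rel=1e-14)
        assert out.relaxation == pytest.approx(relax_free(0.05, 2.0))
        assert out.diffusion == pytest.approx(diffusion_factor(2.3e-9, PFG))

    def test_breakdown_total_is_product_of_parts(self):
        b = AttenuationBreakdown.from_parts(
            relaxation=0.9, diffusion=0.8, convection=0.95, jmod=0.99, extra=0.97
        )
        assert b.total == pytest.approx(
            0.9 * 0.8 * 0.95 * 0.99 * 0.97, rel=1e-13
        )
        with pytest.raises(ValueError):
            AttenuationBreakdown(relaxation=0.9, total=0.5)

    def test_table_like_cube_law(self):
        """f_element = 0.66 over three iterations gives 0.66**3."""
        e = IterationElement(free_delays=[(-math.log(0.66), "transverse")])
        r = RelaxationParams(T1=2.0, T2=1.0)
        out = total_attenuation([e], r, n=3)
        assert out == pytest.approx(0.66**3, rel=1e-12)
        assert out == pytest.approx(0.287496, abs=5e-7)

    @given(
        a=st.integers(min_value=1, max_value=6),
        b=st.integers(min_value=1, max_value=6),
        t=st.floats(min_value=1e-4, max_value=0.2),
    )
    def test_iteration_multiplicativity(self, a, b, t):
        """n = a+b factorises as the product of a- and b-iteration factors."""
        e = IterationElement(free_delays=[(t, "transverse")], pfg_pairs=[PFG])
        r = RelaxationParams(T1=2.0, T2=1.0)
        f_ab = total_attenuation([e], r, D=1e-9, n=a + b)
        f_a = total_attenuation([e], r, D=1e-9, n=a)
        f_b = total_attenuation([e], r, D=1e-9, n=b)
        assert f_ab == pytest.approx(f_a * f_b, rel=1e-10)
        assert f_ab > 0

    def test_convection_breaks_exponent_law_but_follows_parity(self):
        e = IterationElement(free_delays=[(0.01, "transverse")], pfg_pairs=[PFG])
        r = RelaxationParams(T1=2.0, T2=1.0)
        c = ConvectionParams(2e-3)
        f1 = total_attenuation([e], r, n=1, convection=c)
        f2 = total_attenuation([e], r, n=2, convection=c)
        base = element_factor(e, r).total
        assert f2 == pytest.approx(base**2)  # even n: convection gone
        assert f1 == pytest.approx(base * convection_factor(c, PFG))


JSET = [17.2, 10.3, 7.6]


class TestJModulation:
    def test_singlet_and_empty_are_unattenuated(self):
        assert jmod_centerband([], 0.02) == 1.0
        assert jmod_centerband([0.0, 0.0], 0.02) == 1.0
        assert jmod_centerband_exact([], 0.02) == 1.0

    def test_second_order_coefficient(self):
        tau, J = 0.02, 10.0
        expected = 1.0 - math.pi**2 * tau**2 / 24.0 * J**2
        assert jmod_centerband([J], tau) == pytest.approx(expected, rel=1e-14)

    def test_single_coupling_exact_is_sinc(self):
        tau, J = 0.02, 10.0
        x = math.pi * J * tau / 2.0
        assert jmod_centerband_exact([J], tau) == pytest.approx(
            math.sin(x) / x, rel=1e-10
        )

    @pytest.mark.parametrize("tau", [0.005, 0.010, 0.0125, 0.016, 0.020])
    def test_second_order_matches_oracle_for_wide_multiplet(self, tau):
        """Three-coupling multiplet: <1% agreement for chunks up to 20 ms."""
        approx = jmod_centerband(JSET, tau)
        exact = jmod_centerband_exact(JSET, tau)
        assert abs(approx - exact) / exact < 0.01

    def test_error_is_fourth_order_in_tau(self):
        """Halving tau shrinks the approximation error at least 8-fold."""
        taus = [0.004, 0.002, 0.001]
        errs = [
            abs(jmod_centerband(JSET, t) - jmod_centerband_exact(JSET, t))
            for t in taus
        ]
        assert errs[0] / errs[1] >= 8.0
        assert errs[1] / errs[2] >= 8.0

    def test_oversized_couplings_raise_instead_of_clamping(self):
        with pytest.raises(ValueError, match="exact"):
            jmod_centerband([100.0, 90.0], 0.02)

    @given(
        tau=st.floats(min_value=1e-3, max_value=0.02),
        J=st.lists(st.floats(min_value=0.0, max_value=15.0), max_size=4),
    )
    def test_factors_bounded_in_unit_interval(self, tau, J):
        assert 0.0 < jmod_centerband(J, tau) <= 1.0
        assert 0.0 < jmod_centerband_exact(J, tau) <= 1.0
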