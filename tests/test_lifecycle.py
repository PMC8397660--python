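"""Homeostatic cascade, feedbacks, and the ODE right-hand side."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neutrosim.lifecycle import (
    FEEDBACK_CAP,
    InvalidParameterError,
    LifeCycleState,
    PatientTraits,
    derive_homeostatic_parameters,
    feedback_egress,
    feedback_proliferation,
    rhs,
)


class TestCascade:
    @pytest.mark.parametrize(
        "traits_kw, expected",
        [
            (  # glioblastoma column: ratio 3, K_M fraction 0.6
                dict(circ0=4.5e9, ratio_reserv0_circ0=3.0, km_fraction=0.6, gamma=0.02),
                dict(k_elim=0.0231, k_out=0.0077, k_tr4=0.0261,
                     k_tr3_nominal=0.0271, k_tr2=0.0281, k_tr1=0.0291,
                     k_prol=0.0291, reserv0=1.35e10, k_m=2.7e9, v_max=1.952e8),
            ),
            (  # lymphoma column: ratio 2.5, K_M fraction 0.1
                dict(circ0=4.5e9, ratio_reserv0_circ0=2.5, km_fraction=0.1, gamma=0.01),
                dict(k_elim=0.0231, k_out=0.0092, k_tr4=0.0256,
                     k_tr3_nominal=0.0266, k_m=4.5e8, v_max=1.317e8),
            ),
            (  # myeloma column: ratio 2.5, K_M fraction 0.45
                dict(circ0=4.5e9, ratio_reserv0_circ0=2.5, km_fraction=0.45, gamma=0.017),
                dict(k_out=0.0092, k_tr4=0.0256, v_max=1.736e8),
            ),
        ],
        ids=["gbm", "dlbcl", "mm"],
    )
    def test_reproduces_reference_parameter_columns(self, traits_kw, expected):
        """Back-calculated rates match the published values at printed precision."""
        p = derive_homeostatic_parameters(PatientTraits(**traits_kw))
        for name, value in expected.items():
            got = getattr(p, name)
            # printed precision: rates to 4 decimals, concentrations/fluxes
            # to 4 significant figures
            if value < 1:
                assert round(got, 4) == value, name
            else:
                assert float(f"{got:.4g}") == pytest.approx(value), name

    def test_degenerate_cascade_all_rates_equal(self):
        """No maturation death and unit reservoir ratio force every transit
        rate to equal the elimination rate."""
        p = derive_homeostatic_parameters(
            PatientTraits(4.5e9, 1.0, 0.5, 0.01), k_d=0.0
        )
        for name in ("k_out", "k_tr4", "k_tr3_nominal", "k_tr2", "k_tr1", "k_prol"):
            assert getattr(p, name) == pytest.approx(p.k_elim, rel=1e-12)

    def test_cascade_consistency_invariants(self):
        tr = PatientTraits(3.2e9, 2.1, 0.2, 0.015)
        p = derive_homeostatic_parameters(tr, t_half=25.0, k_d=0.002)
        assert p.k_elim == pytest.approx(math.log(2) / 25.0)
        assert p.k_out * p.reserv0 == pytest.approx(p.k_elim * p.circ_homeostatic)
        assert p.k_tr4 * p.tran0 == pytest.approx((p.k_d + p.k_out) * p.reserv0)
        assert p.k_tr3_nominal == pytest.approx(p.k_tr4 + p.k_d)
        assert p.k_tr2 == pytest.approx(p.k_tr3_nominal + p.k_d)
        assert p.k_tr1 == pytest.approx(p.k_tr2 + p.k_d)
        assert p.k_prol == p.k_tr1
        assert p.v_max == pytest.approx(p.k_tr3_nominal * (p.k_m + p.tran0))
        assert p.k_m == pytest.approx(tr.km_fraction * p.tran0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(circ0=-1.0, ratio_reserv0_circ0=2.0, km_fraction=0.1, gamma=0.01),
            dict(circ0=4e9, ratio_reserv0_circ0=0.0, km_fraction=0.1, gamma=0.01),
            dict(circ0=4e9, ratio_reserv0_circ0=2.0, km_fraction=0.0, gamma=0.01),
            dict(circ0=4e9, ratio_reserv0_circ0=2.0, km_fraction=0.1, gamma=-0.5),
        ],
    )
    def test_invalid_traits_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            PatientTraits(**bad)

    def test_invalid_half_life_rejected(self):
        tr = PatientTraits(4e9, 2.0, 0.1, 0.01)
        with pytest.raises(InvalidParameterError):
            derive_homeostatic_parameters(tr, t_half=0.0)
        with pytest.raises(InvalidParameterError):
            derive_homeostatic_parameters(tr, k_d=-0.1)


class TestFeedbacks:
    def test_unity_at_homeostasis(self):
        assert feedback_proliferation(4.5e9, 4.5e9, 0.7) == pytest.approx(1.0)
        assert feedback_egress(4.5e9, 4.5e9, 20.0) == pytest.approx(1.0)
        assert feedback_egress(1e9, 4.5e9, 0.0) == pytest.approx(1.0)

    def test_power_law_values(self):
        # halved transit 2: 2**gamma
        assert feedback_proliferation(2.25e9, 4.5e9, 1.0) == pytest.approx(2.0)
        assert feedback_proliferation(2.25e9, 4.5e9, 0.01) == pytest.approx(
            2 ** 0.01
        )  # = 1.0069556...
        # 10% ANC drop at beta 20: (1/0.9)**20 = 8.2252...
        assert feedback_egress(0.9 * 4.5e9, 4.5e9, 20.0) == pytest.approx(
            (1 / 0.9) ** 20, rel=1e-12
        )

    def test_floor_clamps_and_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="neutrosim.lifecycle"):
            val = feedback_egress(0.0, 4.5e9, 2.0)
        assert "clamping" in caplog.text
        assert val == pytest.approx(min(4.5e9 ** 2, FEEDBACK_CAP))

    def test_cap_bounds_extreme_feedback(self):
        # beta 20 at 1/10th of baseline would give 1e20 uncapped
        assert feedback_egress(4.5e8, 4.5e9, 20.0) == FEEDBACK_CAP

    @given(
        frac=st.floats(0.05, 1.0),
        gamma=st.floats(0.0, 2.0),
    )
    def test_depletion_accelerates_proliferation(self, frac, gamma):
        fb = feedback_proliferation(frac * 4.5e9, 4.5e9, gamma)
        assert fb >= 1.0 - 1e-12
        assert fb <= FEEDBACK_CAP


class TestRHS:
    def test_zero_derivatives_at_homeostatic_state(self, dlbcl_traits):
        p = derive_homeostatic_parameters(dlbcl_traits)
        dy = rhs(p.initial_state(), p, effect=1.0)
        scale = p.initial_state().as_array()
        assert np.all(np.abs(dy) / scale < 1e-9)

    def test_flux_terms_cancel_pairwise(self, dlbcl_traits):
        """Summed derivatives equal production minus apoptosis and elimination:
        every inter-compartment transfer must appear twice with opposite sign."""
        p = derive_homeostatic_parameters(dlbcl_traits)
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.uniform(0.2, 3.0, 6) * p.initial_state().as_array()
            eff = rng.uniform(0.1, 1.0)
            dy = rhs(y, p, effect=eff)
            fb = feedback_proliferation(y[2], p.transit2_homeostatic, p.gamma)
            expected = (
                p.k_prol * fb * y[0]
                - p.k_d * (y[1] + y[2] + y[3] + y[4])
                - p.k_elim * y[5]
            )
            assert np.sum(dy) == pytest.approx(expected, rel=1e-12)

    def test_maturation_flux_equals_nominal_at_homeostasis(self, dlbcl_traits):
        p = derive_homeostatic_parameters(dlbcl_traits)
        flux = p.v_max * p.tran0 / (p.k_m + p.tran0)
        assert flux == pytest.approx(p.k_tr3_nominal * p.tran0, rel=1e-12)

    def test_maturation_flux_saturates_at_scaled_capacity(self, dlbcl_traits):
        """With maximal block (effect 0.1) and transit 2 >> K_M the flux
        asymptotes to 0.1 * v_max."""
        p = derive_homeostatic_parameters(dlbcl_traits)
        y = p.initial_state().as_array().copy()
        y[2] = 1e15  # transit 2 far above K_M
        dy = rhs(y, p, effect=0.1)
        inflow_t3 = dy[3] + (p.k_tr4 + p.k_d) * y[3]
        assert inflow_t3 == pytest.approx(0.1 * p.v_max, rel=1e-5)

    def test_circulation_decays_exponentially_without_inflow(self, dlbcl_traits):
        """With egress shut off, circulating cells die with rate k_elim."""
        from scipy.integrate import solve_ivp

        p = derive_homeostatic_parameters(dlbcl_traits)
        p0 = dataclasses.replace(p, k_out=0.0)
        y0 = p0.initial_state().as_array()
        sol = solve_ivp(
            lambda t, y: rhs(y, p0, 1.0), (0, 96), y0,
            rtol=1e-10, atol=1e-3, dense_output=True,
        )
        t = np.linspace(0, 96, 25)
        circ = sol.sol(t)[5]
        expected = y0[5] * np.exp(-p0.k_elim * t)
        assert np.allclose(circ, expected, rtol=1e-6)

    def test_state_roundtrip(self):
        s = LifeCycleState(1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        assert LifeCycleState.from_array(s.as_array()) == s
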