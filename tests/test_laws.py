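"""Closed-form rate laws, apparent activation energies, transitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratekit import (
    CONST,
    DomainError,
    InputError,
    RateLaw,
    RateLawParams,
    SingularTransitivityError,
    apparent_ea_closed,
    ascc_d,
    eval_rate_law,
    gamma_closed,
    params_from_dict,
    params_to_dict,
)

R = CONST.R_cal


class TestEvalRateLaw:
    def test_arrhenius_enzymatic_value(self):
        # enzymatic-catalysis Arrhenius parameters give k ~ 3 s^-1 at 298.15 K
        p = RateLawParams(RateLaw.ARRHENIUS, A=1.52e11, Ea=14600.0)
        assert eval_rate_law(p, 298.15) == pytest.approx(3.0, rel=0.01)

    def test_am_reduces_to_arrhenius_at_vanishing_d(self):
        am = RateLawParams(RateLaw.AM, A=2.5e3, eps_dd=4000.0, d=1e-10)
        arr = RateLawParams(RateLaw.ARRHENIUS, A=2.5e3, Ea=4000.0)
        T = np.linspace(200.0, 900.0, 25)
        np.testing.assert_allclose(eval_rate_law(am, T), eval_rate_law(arr, T), rtol=1e-6)

    def test_am_anti_arrhenius_value(self, am_anti_params):
        assert eval_rate_law(am_anti_params, 298.15) == pytest.approx(1.13e-13, rel=0.005)

    def test_am_outside_support_raises(self):
        p = RateLawParams(RateLaw.AM, A=1.0, eps_dd=2000.0, d=0.5)
        # base 1 - d*eps/(R T) <= 0 at low temperature for d > 0
        with pytest.raises(DomainError):
            eval_rate_law(p, 100.0)

    def test_vft_below_t0_raises(self):
        p = RateLawParams(RateLaw.VFT, A=1.0, B=-1000.0, T0=200.0)
        with pytest.raises(DomainError):
            eval_rate_law(p, 150.0)

    def test_nonpositive_temperature_raises(self):
        p = RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=1000.0)
        with pytest.raises(DomainError):
            eval_rate_law(p, -5.0)

    @pytest.mark.parametrize(
        "curved,straight",
        [
            (  # ASCC with E_nu = 0 collapses to Arrhenius (derived d = 0)
                RateLawParams(RateLaw.ASCC, A=3.0, eps_dd=2441.0, E_nu=0.0),
                RateLawParams(RateLaw.ARRHENIUS, A=3.0, Ea=2441.0),
            ),
            (  # NTS -> Arrhenius as T0 -> 0
                RateLawParams(RateLaw.NTS, A=3.0, E0=1655.0, T0=1e-6),
                RateLawParams(RateLaw.ARRHENIUS, A=3.0, Ea=1655.0),
            ),
            (  # VFT -> Arrhenius (Ea = -B R) as T0 -> 0
                RateLawParams(RateLaw.VFT, A=3.0, B=-700.0, T0=1e-8),
                RateLawParams(RateLaw.ARRHENIUS, A=3.0, Ea=700.0 * R),
            ),
        ],
    )
    def test_limiting_equivalences(self, curved, straight):
        T = np.linspace(220.0, 880.0, 30)
        np.testing.assert_allclose(
            eval_rate_law(curved, T), eval_rate_law(straight, T), rtol=1e-6
        )


class TestApparentEa:
    def test_arrhenius_is_constant(self):
        p = RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=1000.0)
        T = np.linspace(100.0, 1000.0, 7)
        np.testing.assert_allclose(apparent_ea_closed(p, T), 1000.0)

    def test_am_anti_arrhenius_negative_ea(self, am_anti_params):
        ea = apparent_ea_closed(am_anti_params, 298.15)
        assert ea == pytest.approx(-193.3, rel=0.005)

    @pytest.mark.parametrize(
        "params",
        [
            RateLawParams(RateLaw.ARRHENIUS, A=2.0, Ea=4000.0),
            RateLawParams(RateLaw.AM, A=1.11e-10, eps_dd=9170.0, d=-0.086),
            RateLawParams(RateLaw.AM, A=7.43e-14, eps_dd=-324.61, d=1.24),
            RateLawParams(RateLaw.ASCC, A=2.33e4, eps_dd=2441.0, E_nu=429.0),
            RateLawParams(RateLaw.NTS, A=3.12e4, E0=1655.0, T0=168.0),
            RateLawParams(RateLaw.VFT, A=1.25e5, B=-1298.0, T0=175.0),
        ],
        ids=["arrhenius", "am-sub", "am-anti", "ascc", "nts", "vft"],
    )
    def test_matches_finite_difference_of_log_rate(self, params):
        """Analytic -d ln k/d beta vs centered finite differences, all laws."""
        T = np.linspace(250.0, 420.0, 9)
        beta = 1.0 / (R * T)
        h = 1e-6 * beta
        lnk = lambda b: np.log(eval_rate_law(params, 1.0 / (R * b)))
        fd = -(lnk(beta + h) - lnk(beta - h)) / (2.0 * h)
        np.testing.assert_allclose(apparent_ea_closed(params, T), fd, rtol=1e-6)

    def test_am_curvature_sign_follows_deformation(self):
        """d < 0 gives concave (sub-Arrhenius) ln k vs beta, d > 0 convex."""
        T = np.linspace(260.0, 400.0, 41)
        beta = 1.0 / (R * T)[::-1]
        for d, sign in [(-0.3, 1.0), (0.12, -1.0)]:
            p = RateLawParams(RateLaw.AM, A=1.0, eps_dd=3000.0, d=d)
            lnk = np.log(eval_rate_law(p, 1.0 / (R * beta)))
            second = np.gradient(np.gradient(lnk, beta), beta)[2:-2]
            assert np.all(sign * second > 0.0)


class TestGamma:
    def test_reciprocal_of_constant_ea(self):
        p = RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=1000.0)
        beta = 1.0 / (R * np.linspace(200.0, 800.0, 11))
        np.testing.assert_allclose(gamma_closed(p, beta), 1e-3)

    def test_am_affine_form(self):
        p = RateLawParams(RateLaw.AM, A=1.0, eps_dd=9170.0, d=-0.086)
        beta = 1.0 / (R * 300.0)
        assert gamma_closed(p, beta) == pytest.approx(1.0 / 9170.0 + 0.086 * beta, rel=1e-12)
        # and it agrees with the generic reciprocal route
        assert gamma_closed(p, beta) == pytest.approx(
            1.0 / apparent_ea_closed(p, 300.0), rel=1e-12
        )

    def test_am_affine_interpolation_exact(self):
        """gamma(beta) for AM is exactly affine: two points predict the rest."""
        p = RateLawParams(RateLaw.AM, A=1.0, eps_dd=318.06, d=-0.81)
        beta = 1.0 / (R * np.linspace(120.0, 300.0, 50))
        g = gamma_closed(p, beta)
        slope = (g[-1] - g[0]) / (beta[-1] - beta[0])
        predicted = g[0] + slope * (beta - beta[0])
        np.testing.assert_allclose(g, predicted, rtol=1e-12)

    def test_zero_ea_is_singular(self):
        p = RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=0.0)
        with pytest.raises(SingularTransitivityError):
            gamma_closed(p, np.array([1e-3]))


class TestAsccD:
    def test_values(self):
        assert ascc_d(2441.0, 0.0) == 0.0
        assert ascc_d(2441.0, 429.0) == pytest.approx(-2.574e-3, rel=1e-3)
        assert ascc_d(1000.0, 1000.0) == pytest.approx(-1.0 / 12.0)

    def test_zero_barrier_rejected(self):
        with pytest.raises(DomainError):
            ascc_d(0.0, 400.0)


class TestParamsRecord:
    def test_foreign_field_rejected(self):
        with pytest.raises(InputError):
            RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=10.0, d=0.5)

    def test_missing_field_rejected(self):
        with pytest.raises(InputError):
            RateLawParams(RateLaw.AM, A=1.0, eps_dd=10.0)

    def test_flat_dict_round_trip(self, am_sub_params):
        again = params_from_dict(params_to_dict(am_sub_params))
        assert again == am_sub_params

    def test_unknown_law_rejected(self):
        with pytest.raises(InputError):
            params_from_dict({"law": "kooij", "A": 1.0})


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    eps=st.floats(-5000.0, 9000.0).filter(lambda x: abs(x) > 50.0),
    d=st.floats(-1.5, 1.5),
    logA=st.floats(-12.0, 10.0),
)
def test_am_ea_consistent_with_numerical_slope(eps, d, logA):
    """Property: AM closed-form Ea equals the finite-difference slope wherever
    the law is supported on a mid-range temperature window."""
    p = RateLawParams(RateLaw.AM, A=10.0 ** logA, eps_dd=eps, d=d)
    T = np.linspace(400.0, 500.0, 5)
    beta = 1.0 / (R * T)
    if np.any(1.0 - d * eps * beta * 1.001 <= 0.0):
        return  # outside support; evaluation would (correctly) raise
    h = 1e-6 * beta
    fd = -(
        np.log(eval_rate_law(p, 1.0 / (R * (beta + h))))
        - np.log(eval_rate_law(p, 1.0 / (R * (beta - h))))
    ) / (2.0 * h)
    np.testing.assert_allclose(apparent_ea_closed(p, T), fd, rtol=2e-5, atol=1e-7)
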