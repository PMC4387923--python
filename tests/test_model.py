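"""Core model: sigmoid, right-hand side, equilibria."""

import math

import numpy as np
import pytest

from canaryresp import (
    DriveSet,
    ERCoupling,
    ModelParams,
    NetworkState,
    RACoupling,
    RateConstants,
    find_equilibria,
    rhs,
    sigmoid,
)

# value of 1/(1 + e^7.5) computed symbolically to 20 digits
SIGMOID_MINUS_7P5 = 0.00055277863692359951608


def decoupled_params(bias: float) -> ModelParams:
    """A network whose e_er unit is isolated with a pure bias input."""
    er = ERCoupling(
        alpha_eer_F=0.0, alpha_eer_ra=0.0, alpha_ier_ra=0.0,
        bias_e=bias, bias_i=bias, w_ee=0.0, w_ei=0.0, w_ie=0.0, w_ii=0.0,
    )
    ra = RACoupling(bias, 0, 0, 0, 0, bias, 0, 0, 0, 0)
    return ModelParams(er=er, ra=ra)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    def test_reference_value(self):
        assert sigmoid(-7.5) == pytest.approx(SIGMOID_MINUS_7P5, rel=1e-12)

    def test_strictly_increasing(self):
        assert sigmoid(2.0) > sigmoid(1.0)
        xs = np.linspace(-20, 20, 101)
        assert np.all(np.diff(sigmoid(xs)) > 0)

    @pytest.mark.parametrize("x,expected", [(800.0, 1.0), (-800.0, 0.0)])
    def test_saturates_without_overflow(self, x, expected):
        assert sigmoid(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError):
            sigmoid(bad)

    def test_array_input(self):
        out = sigmoid(np.array([0.0, -7.5]))
        assert out.shape == (2,)
        assert out[0] == 0.5


class TestRhs:
    def test_positive_at_origin(self, p0_params):
        """At the origin with no drive every derivative is rate*S(bias) > 0."""
        d = rhs(NetworkState(0, 0, 0, 0), 0.0, p0_params, DriveSet())
        assert np.all(d > 0)
        r = p0_params.rates
        expected = np.array(
            [r.r_er * sigmoid(-7.5), r.r_er * sigmoid(-11.5),
             r.r_ra * sigmoid(-3.0), r.r_ra * sigmoid(-6.0)]
        )
        np.testing.assert_allclose(d, expected, rtol=1e-12)

    def test_drive_raises_e_er_derivative(self, p0_params):
        """With a positive F gain, turning the drive on increases d(e_er)/dt."""
        state = NetworkState(0.2, 0.1, 0.3, 0.2)
        from canaryresp import SquarePulse

        quiet = rhs(state, 200.0, p0_params, DriveSet())
        driven = rhs(
            state, 10.0, p0_params, DriveSet(F=(SquarePulse(0.0, 20.0, 10.0),))
        )
        assert driven[0] > quiet[0]
        np.testing.assert_allclose(driven[1:], quiet[1:], rtol=1e-12)

    def test_zero_at_equilibrium(self, p0_params):
        roots = find_equilibria(p0_params)
        assert roots
        for s in roots:
            assert np.linalg.norm(rhs(s, 0.0, p0_params, DriveSet())) < 1e-9

    def test_monotone_in_coupled_inputs(self, p0_params):
        """Each derivative moves with the sign of the printed coefficient."""
        base = NetworkState(0.3, 0.2, 0.4, 0.3)
        d0 = rhs(base, 0.0, p0_params, DriveSet())
        # alpha_eer_ra = +10: more e_ra raises d(e_er)/dt
        up = rhs(NetworkState(0.3, 0.2, 0.5, 0.3), 0.0, p0_params, DriveSet())
        assert up[0] > d0[0]
        # w_ei = -10: more i_er lowers d(e_er)/dt
        up = rhs(NetworkState(0.3, 0.3, 0.4, 0.3), 0.0, p0_params, DriveSet())
        assert up[0] < d0[0]
        # b_e_ra = -3: more i_ra lowers d(e_ra)/dt
        up = rhs(NetworkState(0.3, 0.2, 0.4, 0.4), 0.0, p0_params, DriveSet())
        assert up[2] < d0[2]

    def test_rejects_non_finite_time(self, p0_params):
        with pytest.raises(ValueError):
            rhs(NetworkState(0, 0, 0, 0), float("nan"), p0_params, DriveSet())


class TestEquilibria:
    def test_off_state_exists_at_rest(self, p0_params):
        """The resting network has a low-activity (off) fixed point."""
        roots = find_equilibria(p0_params)
        assert any(s.e_er < 0.5 for s in roots)

    def test_decoupled_unit_fixed_point_is_sigmoid_of_bias(self):
        params = decoupled_params(-1.3)
        roots = find_equilibria(params)
        assert len(roots) == 1
        assert roots[0].e_er == pytest.approx(sigmoid(-1.3), abs=1e-10)

    def test_residual_below_tolerance(self, p0_params):
        for s in find_equilibria(p0_params):
            assert np.linalg.norm(rhs(s, 0.0, p0_params, DriveSet())) < 1e-10

    def test_invariant_to_rate_constants(self, p0_params):
        from dataclasses import replace

        fast = replace(p0_params, rates=RateConstants(r_er=3.0 / 4, r_ra=1.0 / 3))
        a = find_equilibria(p0_params)
        b = find_equilibria(fast)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.as_array(), y.as_array(), atol=1e-8)

    def test_sorted_by_e_er(self):
        # bistable single unit: strong self-excitation, no inhibition
        er = ERCoupling(0.0, 0.0, 0.0, bias_e=-5.0, w_ee=10.0,
                        w_ei=0.0, w_ie=0.0, w_ii=0.0, bias_i=-11.5)
        ra = RACoupling(-5, 0, 0, 0, 0, -5, 0, 0, 0, 0)
        roots = find_equilibria(ModelParams(er=er, ra=ra), n_starts=256)
        assert len(roots) >= 2
        e_vals = [s.e_er for s in roots]
        assert e_vals == sorted(e_vals)

    def test_n_starts_validation(self, p0_params):
        with pytest.raises(ValueError):
            find_equilibria(p0_params, n_starts=0)


class TestModelParams:
    def test_dict_round_trip(self, p0_params):
        assert ModelParams.from_dict(p0_params.to_dict()) == p0_params

    def test_rejects_unknown_keys(self, p0_params):
        d = p0_params.to_dict()
        d["er"]["mystery"] = 1.0
        with pytest.raises(ValueError, match="mystery"):
            ModelParams.from_dict(d)

    def test_rates_must_be_positive(self):
        with pytest.raises(ValueError):
            RateConstants(r_er=0.0)
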