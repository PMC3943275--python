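import math

import numpy as np
import pytest

import semgcodec as sc
from semgcodec.errors import ParameterError

GRID = [(q, l, m)
        for m in (4, 8, 16, 32)
        for q in range(4, 16)
        for l in range(1, q)]


class TestDLA:
    def test_endpoints(self):
        b = sc.allocate_dla(7, 1, 16).bits
        assert b[0] == 7 and b[15] == 1

    def test_interior_value_is_ceiling(self):
        # Q=7, L=1, M=16: B[8] = ceil(7 - 0.4*8) = ceil(3.8) = 4
        assert sc.allocate_dla(7, 1, 16).bits[8] == 4

    def test_flat_when_q_equals_l(self):
        assert (sc.allocate_dla(5, 5, 16).bits == 5).all()

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            sc.allocate_dla(3, 5, 16)
        with pytest.raises(ParameterError):
            sc.allocate_dla(7, 1, 1)


class TestDSR:
    def test_curve_constant_matches_closed_form(self):
        # C = Q^2 (1-M) / (L^2 - Q^2) = 49*(-15)/(1-49) = 15.3125
        c = 7 * 7 * (1 - 16) / (1 - 49)
        assert c == pytest.approx(15.3125)
        # and both closures of xi agree: Q/sqrt(C) == L/sqrt(C+1-M)
        assert 7 / math.sqrt(c) == pytest.approx(1 / math.sqrt(c + 1 - 16))

    def test_endpoints_and_monotone(self):
        b = sc.allocate_dsr(7, 1, 16).bits
        assert b[0] == 7 and b[15] == 1
        assert (np.diff(b) <= 0).all()

    def test_flat_fallback(self):
        assert (sc.allocate_dsr(6, 6, 8).bits == 6).all()


class TestDEA:
    def test_exponent_closed_form(self):
        # Q=8, L=2, M=16: log10(2)/log10(8) = 1/3, p = (1-16)/(1/3-1) = 22.5
        p = (1 - 16) / (math.log10(2) / math.log10(8) - 1)
        assert p == pytest.approx(22.5)

    def test_endpoints(self):
        b = sc.allocate_dea(8, 2, 16).bits
        assert b[0] == 8 and b[15] == 2

    def test_values_stay_within_q_l(self):
        for q, l, m in [(8, 2, 16), (15, 2, 32), (10, 3, 8), (5, 2, 4)]:
            b = sc.allocate_dea(q, l, m).bits
            assert b.min() >= l and b.max() <= q

    def test_log_degenerate_rejected(self):
        with pytest.raises(ParameterError):
            sc.allocate_dea(8, 1, 16)


class TestRHT:
    def test_alpha_zero_is_flat_half_q(self):
        b = sc.allocate_rht(10, 0, 16, alpha=0.0).bits
        assert (b == 5).all()  # ceil(Q/2) everywhere before clamping

    def test_midpoint_value(self):
        # m = M*beta integer: tanh(0) = 0 so B = ceil(Q/2)
        b = sc.allocate_rht(9, 1, 16, alpha=0.7, beta=0.5).bits
        assert b[8] == 5

    def test_saturation_at_large_alpha(self):
        b = sc.allocate_rht(10, 1, 16, alpha=50.0, beta=0.5).bits
        assert (b[:8] == 10).all()
        assert (b[9:] == 1).all()  # clamped up to L

    def test_clamped_into_l_q(self):
        b = sc.allocate_rht(12, 4, 16, alpha=2.0).bits
        assert b.min() >= 4 and b.max() <= 12


class TestSharedProperties:
    def test_endpoint_property_over_grid(self):
        for q, l, m in GRID:
            for fn in (sc.allocate_dla, sc.allocate_dsr):
                b = fn(q, l, m).bits
                assert b[0] == q and b[m - 1] == l, (fn.__name__, q, l, m)
            if l >= 2:
                b = sc.allocate_dea(q, l, m).bits
                assert b[0] == q and b[m - 1] == l, ("dea", q, l, m)

    def test_monotone_non_increasing_over_grid(self):
        for q, l, m in GRID:
            shapes = [sc.allocate_dla(q, l, m), sc.allocate_dsr(q, l, m),
                      sc.allocate_rht(q, l, m, alpha=0.4)]
            if l >= 2:
                shapes.append(sc.allocate_dea(q, l, m))
            for plan in shapes:
                assert (np.diff(plan.bits) <= 0).all(), (plan.shape, q, l, m)

    def test_bit_budget_increases_with_q(self):
        for shape in sc.SHAPES:
            budgets = [sc.allocate(shape, q, 2, 16).bits.sum()
                       for q in range(3, 16)]
            assert (np.diff(budgets) > 0).all(), shape


class TestScaleFactorsAndSubbands:
    @pytest.mark.parametrize("bits, lam", [(7, 128), (0, 1), (15, 32768)])
    def test_scale_factor_is_exact_power(self, bits, lam):
        plan = sc.AllocationPlan("dla", 2, bits, bits,
                                 np.array([bits, bits]))
        assert plan.scale_factors[0] == lam
        assert sc.scale_factors(plan)[1] == lam

    @pytest.mark.parametrize("k, m", [(0, 0), (127, 0), (128, 1), (2047, 15)])
    def test_subband_mapping(self, k, m):
        assert sc.subband_of(k, 2048, 16) == m

    def test_subband_divisibility_error(self):
        with pytest.raises(ParameterError):
            sc.subband_of(0, 2048, 15)

    def test_dispatch_unknown_shape(self):
        with pytest.raises(ParameterError):
            sc.allocate("cubic", 8, 2, 16)
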