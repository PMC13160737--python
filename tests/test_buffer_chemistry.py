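import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from srlumen.buffer_chemistry import (
    BufferState,
    bound_from_total,
    effective_diffusion_coefficient,
    free_from_total,
    free_total_slope,
    total_from_free,
)

CASQ, KD, DCA = 6.1, 1.1, 3e-10

conc = st.floats(min_value=1e-6, max_value=1e2, allow_nan=False)


def brentq_bound(ca_total, casq_total, Kd):
    """Independent oracle: bracketed root of the mass-action equation
    b^2 - (t + c + Kd) b + t c = 0 on [0, min(t, c)]."""
    if ca_total == 0 or casq_total == 0:
        return 0.0
    f = lambda b: b * b - (ca_total + casq_total + Kd) * b + ca_total * casq_total
    hi = min(ca_total, casq_total)
    return brentq(f, 0.0, hi, xtol=1e-16, rtol=1e-15)


class TestClosedForms:
    def test_total_from_free_published_value(self):
        # 3.6 mM free with 6.1 mM calsequestrin, Kd 1.1 mM -> 8.2723 mM total
        assert total_from_free(3.6, CASQ, KD) == pytest.approx(8.2723, abs=5e-5)

    @pytest.mark.parametrize(
        "func,args,expected",
        [
            (total_from_free, (2.5, 0.0, KD), 2.5),      # no buffer: total = free
            (total_from_free, (0.0, CASQ, KD), 0.0),     # no calcium
            (bound_from_total, (7.0, 0.0, KD), 0.0),
            (bound_from_total, (0.0, CASQ, KD), 0.0),
            (free_from_total, (7.0, 0.0, KD), 7.0),
            (free_from_total, (0.0, CASQ, KD), 0.0),
        ],
    )
    def test_degenerate_inputs(self, func, args, expected):
        assert func(*args) == pytest.approx(expected, abs=1e-14)

    def test_bound_from_total_against_bracketing_oracle(self):
        # frozen from the oracle: bound(8.2723, 6.1, 1.1) = 8.2723 - 3.6
        assert bound_from_total(8.2723, CASQ, KD) == pytest.approx(brentq_bound(8.2723, CASQ, KD), rel=1e-12)
        assert bound_from_total(8.2723, CASQ, KD) == pytest.approx(4.6723, abs=5e-5)

    def test_free_from_total_inverts_total_from_free(self):
        assert free_from_total(8.2723, CASQ, KD) == pytest.approx(3.6000, abs=5e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            total_from_free(-1.0, CASQ, KD)
        with pytest.raises(ValueError):
            free_from_total(1.0, CASQ, -KD)

    def test_vectorized_matches_scalar(self):
        totals = np.array([0.0, 0.5, 3.6, 8.2723, 50.0])
        vec = free_from_total(totals, CASQ, KD)
        assert vec.shape == totals.shape
        for t, v in zip(totals, vec):
            assert free_from_total(float(t), CASQ, KD) == pytest.approx(v, rel=1e-14, abs=1e-300)


class TestEquilibriumProperties:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(free=conc, casq=st.floats(min_value=0, max_value=50), kd=st.floats(min_value=1e-3, max_value=10))
    def test_round_trip_free_total_free(self, free, casq, kd):
        total = total_from_free(free, casq, kd)
        assert free_from_total(total, casq, kd) == pytest.approx(free, rel=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(total=conc, casq=st.floats(min_value=0, max_value=50), kd=st.floats(min_value=1e-3, max_value=10))
    def test_conservation_and_bounds(self, total, casq, kd):
        free = free_from_total(total, casq, kd)
        bound = bound_from_total(total, casq, kd)
        assert free + bound == pytest.approx(total, rel=1e-10)
        assert 0 <= free <= total
        assert bound <= min(total, casq) + 1e-12

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(total=conc, casq=st.floats(min_value=0, max_value=50), kd=st.floats(min_value=1e-3, max_value=10))
    def test_quadratic_root_matches_bracketing_solver(self, total, casq, kd):
        assert bound_from_total(total, casq, kd) == pytest.approx(brentq_bound(total, casq, kd), rel=1e-8, abs=1e-12)

    def test_free_strictly_increasing_with_unit_lipschitz_bound(self):
        totals = np.linspace(1e-6, 100, 4001)
        free = free_from_total(totals, CASQ, KD)
        slopes = np.diff(free) / np.diff(totals)
        assert np.all(slopes > 0)
        assert np.all(slopes <= 1 + 1e-12)
        # analytic slope agrees with the finite difference
        mid = free_total_slope(0.5 * (totals[:-1] + totals[1:]), CASQ, KD)
        assert np.allclose(slopes, mid, rtol=1e-4)


class TestEffectiveDiffusivity:
    def test_published_operating_point(self):
        # D* = D_Ca * 3.6 / 8.2723 at the resting composition
        d = effective_diffusion_coefficient(8.2723, CASQ, KD, DCA)
        assert d == pytest.approx(1.3056e-10, rel=1e-4)

    def test_no_buffer_gives_free_diffusivity(self):
        assert effective_diffusion_coefficient(5.0, 0.0, KD, DCA) == pytest.approx(DCA)

    def test_bounded_and_monotone_in_buffer(self):
        casqs = np.array([0.0, 1.0, 6.1, 50.0, 500.0])
        ds = np.array([effective_diffusion_coefficient(8.2723, c, KD, DCA) for c in casqs])
        assert np.all(ds > 0)
        assert np.all(ds <= DCA)
        assert np.all(np.diff(ds) < 0)  # more buffer, slower transport

    def test_zero_total_limit_is_continuous(self):
        limit = effective_diffusion_coefficient(0.0, CASQ, KD, DCA)
        assert limit == pytest.approx(DCA * KD / (KD + CASQ), rel=1e-12)
        near = effective_diffusion_coefficient(1e-10, CASQ, KD, DCA)
        assert near == pytest.approx(limit, rel=1e-6)


class TestBufferState:
    def test_constructors_agree(self):
        a = BufferState.from_free(3.6, CASQ, KD)
        b = BufferState.from_total(a.ca_total, CASQ, KD)
        assert b.ca_free == pytest.approx(3.6, rel=1e-12)
        assert a.casq_bound + a.casq_free == pytest.approx(CASQ, rel=1e-12)

    def test_inconsistent_state_rejected(self):
        with pytest.raises(ValueError):
            BufferState(ca_total=8.0, ca_free=3.6, casq_bound=1.0, casq_free=5.1, casq_total=6.1, Kd=KD)
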