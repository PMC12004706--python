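"""Markov model: closed forms, generator structure, propagation, equilibrium."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navblock.model import (
    STATES,
    DrugParams,
    GatingParams,
    Propagator,
    equilibrium_apparent_ic50,
    equilibrium_block,
    equilibrium_state,
    free_equilibrium_state,
    propagate,
    rate_matrix,
    steady_state_availability,
)

IDX = {s: i for i, s in enumerate(STATES)}


class TestAvailability:
    def test_midpoint_is_half(self, gating):
        assert steady_state_availability(gating, gating.ssi_v_half) == pytest.approx(0.5)

    def test_value_at_minus_100(self, gating):
        # logistic with midpoint -80 mV and slope 8 mV
        assert steady_state_availability(gating, -100.0) == pytest.approx(0.9241418, abs=1e-6)

    def test_value_at_minus_120(self, gating):
        assert steady_state_availability(gating, -120.0) == pytest.approx(0.99331, abs=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(v=st.floats(-150, 40), dv=st.floats(0.1, 20))
    def test_monotonically_decreasing(self, gating, v, dv):
        assert steady_state_availability(gating, v + dv) < steady_state_availability(gating, v)


class TestApparentIC50:
    def test_rested_limit_is_kr(self, drug):
        assert equilibrium_apparent_ic50(drug, 1.0) == pytest.approx(drug.k_r)

    def test_inactivated_limit_is_ki(self, drug):
        assert equilibrium_apparent_ic50(drug, 0.0) == pytest.approx(3.6)

    def test_mixed_availability(self, drug):
        # 1 / (0.924/108 + 0.076/3.6)
        assert equilibrium_apparent_ic50(drug, 0.924) == pytest.approx(33.7079, abs=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(h=st.floats(0, 1))
    def test_bounded_by_the_two_constants(self, drug, h):
        ic = equilibrium_apparent_ic50(drug, h)
        tol = 1e-12
        assert drug.k_i * (1 - tol) <= ic <= drug.k_r * (1 + tol)

    def test_availability_out_of_range(self, drug):
        with pytest.raises(ValueError):
            equilibrium_apparent_ic50(drug, 1.2)


class TestRateMatrix:
    @pytest.mark.parametrize("v,conc", [(-120, 0), (-80, 30), (-20, 100), (25, 3)])
    def test_generator_structure(self, gating, drug, v, conc):
        Q = rate_matrix(gating, drug, v, conc)
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_no_binding_at_zero_concentration(self, gating, drug):
        Q = rate_matrix(gating, drug, -90.0, 0.0)
        for free, bound in (("C", "CB"), ("IF", "IFB"), ("IS", "ISB")):
            assert Q[IDX[bound], IDX[free]] == 0.0

    def test_no_open_state_binding(self, gating, drug):
        Q = rate_matrix(gating, drug, -90.0, 30.0)
        for bound in ("CB", "IFB", "ISB"):
            assert Q[IDX[bound], IDX["O"]] == 0.0
            assert Q[IDX["O"], IDX[bound]] == 0.0

    def test_binding_cycle_detailed_balance(self, gating, drug):
        """Product of rate ratios around C -> CB -> IFB -> IF -> C equals 1."""
        Q = rate_matrix(gating, drug, -85.0, 10.0)

        def r(a, b):
            return Q[IDX[b], IDX[a]]

        fwd = r("C", "CB") * r("CB", "IFB") * r("IFB", "IF") * r("IF", "C")
        back = r("CB", "C") * r("IFB", "CB") * r("IF", "IFB") * r("C", "IF")
        assert fwd / back == pytest.approx(1.0, rel=1e-12)

    def test_unbinding_over_binding_ratio_is_ki(self, gating, drug):
        conc = 7.0
        Q = rate_matrix(gating, drug, -100.0, conc)
        ratio = Q[IDX["IF"], IDX["IFB"]] / (Q[IDX["IFB"], IDX["IF"]] / conc)
        assert ratio == pytest.approx(drug.k_i)

    def test_bound_inactivation_shifted_by_state_preference(self, gating, drug):
        """Thermodynamic consistency: the drug-bound inactivation equilibrium
        constant exceeds the free one by exactly K_R / K_I."""
        Q = rate_matrix(gating, drug, -90.0, 5.0)
        free = Q[IDX["IF"], IDX["C"]] / Q[IDX["C"], IDX["IF"]]
        bound = Q[IDX["IFB"], IDX["CB"]] / Q[IDX["CB"], IDX["IFB"]]
        assert bound / free == pytest.approx(drug.k_r / drug.k_i, rel=1e-12)

    def test_negative_concentration_rejected(self, gating, drug):
        with pytest.raises(ValueError):
            rate_matrix(gating, drug, -90.0, -1.0)


def _two_state_Q(a: float, b: float) -> np.ndarray:
    """7-state generator with dynamics confined to the first two states."""
    Q = np.zeros((7, 7))
    Q[0, 0], Q[1, 0] = -a, a
    Q[1, 1], Q[0, 1] = -b, b
    return Q


class TestPropagate:
    def test_zero_duration_is_identity(self):
        s = np.array([0.3, 0.7, 0, 0, 0, 0, 0])
        assert np.allclose(propagate(s, _two_state_Q(1.0, 2.0), 0.0), s)

    def test_two_state_equilibrium(self):
        s = np.array([1.0, 0, 0, 0, 0, 0, 0])
        out = propagate(s, _two_state_Q(0.5, 0.5), 1e4)
        assert out[0] == pytest.approx(0.5, abs=1e-9)
        assert out[1] == pytest.approx(0.5, abs=1e-9)

    def test_two_state_relaxation_time_constant(self):
        a, b = 0.7, 0.3
        s = np.array([1.0, 0, 0, 0, 0, 0, 0])
        tau = 1.0 / (a + b)
        out = propagate(s, _two_state_Q(a, b), tau)
        eq = b / (a + b)
        expected = eq + (1 - eq) * math.exp(-1.0)
        assert out[0] == pytest.approx(expected, abs=1e-10)

    def test_occupancy_conserved_over_long_protocol_like_evolution(self, gating, drug):
        state = free_equilibrium_state(gating, drug, -120.0)
        for v, dur in [(-120, 5000), (0, 20), (-80, 980), (-20, 500), (-120, 60000)] * 4:
            state = Propagator(rate_matrix(gating, drug, v, 30.0)).advance(state, dur)
        assert state.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(state >= 0)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            propagate(np.array([0.5, 0.6, 0, 0, 0, 0, 0]), _two_state_Q(1, 1), 1.0)


class TestEquilibrium:
    def test_vehicle_equilibrium_has_no_bound_occupancy(self, gating, drug):
        s = equilibrium_state(gating, drug, -100.0, 0.0)
        assert s.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(s[4:] == pytest.approx(0.0, abs=1e-12))

    def test_free_init_keeps_bound_empty_when_propagated_without_drug(self, gating, drug):
        s = free_equilibrium_state(gating, drug, -110.0)
        out = propagate(s, rate_matrix(gating, drug, -110.0, 0.0), 1e5)
        assert np.all(out[4:] <= 1e-12)

    def test_equilibrium_matches_gibbs_weights(self, gating, drug):
        v, conc = -95.0, 12.0
        s = equilibrium_state(gating, drug, v, conc)
        x = math.exp((v - gating.ssi_v_half) / gating.ssi_slope)
        o = math.exp((v - gating.act_v_half) / gating.act_slope)
        r = gating.slow_ratio
        w = np.array(
            [
                1.0,
                o,
                x / (1 + r),
                x * r / (1 + r),
                conc / drug.k_r,
                x / (1 + r) * conc / drug.k_i,
                x * r / (1 + r) * conc / drug.k_i,
            ]
        )
        assert np.allclose(s, w / w.sum(), atol=1e-9)

    def test_block_monotone_with_depolarization(self, gating, drug):
        blocks = [equilibrium_block(gating, drug, v, 30.0) for v in range(-120, -60, 5)]
        assert all(b2 > b1 for b1, b2 in zip(blocks, blocks[1:]))
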