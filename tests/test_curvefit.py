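"""Fitting primitives: round trips, invariances, degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navblock.curvefit import (
    BiexpFit,
    FitError,
    HillFit,
    IVRecord,
    NoInhibition,
    boltzmann,
    conductance_from_iv,
    estimate_reversal,
    fit_biexp,
    fit_boltzmann,
    fit_hill,
    fit_monoexp,
    hill,
    nernst_potential,
)

CONCS = np.array([1.0, 3.0, 10.0, 30.0, 100.0])


class TestHill:
    def test_midpoint_evaluates_to_half(self):
        assert hill(np.array([6.7]), 6.7, 1.0)[0] == pytest.approx(0.5)

    def test_printed_value_consistency(self):
        # 30 uM against an apparent IC50 of 96.5 uM, unit slope -> ~24%
        assert hill(np.array([30.0]), 96.5, 1.0)[0] == pytest.approx(0.237, abs=5e-4)

    @pytest.mark.parametrize("ic50,h", [(6.7, 1.0), (96.5, 1.0), (15.0, 0.8)])
    def test_noiseless_round_trip(self, ic50, h):
        fit = fit_hill(CONCS, hill(CONCS, ic50, h))
        assert isinstance(fit, HillFit)
        assert fit.ic50 == pytest.approx(ic50, rel=1e-6)
        assert fit.hill == pytest.approx(h, rel=1e-6)

    def test_fixed_slope_is_exact(self):
        fit = fit_hill(CONCS, hill(CONCS, 20.0, 1.0), fix_slope=1.0)
        assert fit.slope_fixed and fit.hill == 1.0
        assert fit.ic50 == pytest.approx(20.0, rel=1e-6)

    def test_no_inhibition_flag(self):
        flat = np.full_like(CONCS, 0.02)
        out = fit_hill(CONCS, flat)
        assert isinstance(out, NoInhibition)
        assert out.max_response == pytest.approx(0.02)

    def test_too_few_concentrations(self):
        with pytest.raises(FitError):
            fit_hill([10.0, 10.0, 30.0], [0.4, 0.45, 0.7])

    def test_out_of_range_responses_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(CONCS, [0.1, 0.2, 0.5, 0.9, 1.5])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.sampled_from([1e-3, 1.0, 1e3]))
    def test_concentration_unit_invariance(self, scale):
        y = hill(CONCS, 12.0, 1.1)
        fit = fit_hill(CONCS * scale, y)
        assert fit.ic50 == pytest.approx(12.0 * scale, rel=1e-5)
        assert fit.hill == pytest.approx(1.1, rel=1e-5)

    def test_seeded_noise_robustness(self):
        """5% multiplicative noise, 8 replicates per point: the fitted IC50
        lands within 15% of truth in at least 95% of 200 repetitions."""
        rng = np.random.default_rng(20260920)
        truth = 15.0
        hits = 0
        y0 = hill(CONCS, truth, 1.0)
        for _ in range(200):
            reps = y0[None, :] * rng.normal(1.0, 0.05, size=(8, len(CONCS)))
            fit = fit_hill(CONCS, np.clip(reps.mean(axis=0), -0.2, 1.2))
            hits += abs(fit.ic50 - truth) / truth < 0.15
        assert hits >= 190


class TestBoltzmann:
    def test_midpoint_is_half_amplitude(self):
        assert boltzmann(np.array([-80.0]), -80.0, 8.0, 1.0, "inactivation")[0] == 0.5

    @pytest.mark.parametrize("direction,v_half,k", [("inactivation", -80.0, 8.0), ("activation", -37.0, 7.0)])
    def test_noiseless_round_trip(self, direction, v_half, k):
        v = np.arange(-120.0, 30.0, 5.0)
        fit = fit_boltzmann(v, boltzmann(v, v_half, k, 1.0, direction), direction)
        assert fit.v_half == pytest.approx(v_half, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.k > 0

    def test_availability_convention(self):
        v = np.arange(-120.0, 30.0, 5.0)
        fit = fit_boltzmann(v, boltzmann(v, -80, 8, 1.0, "inactivation"), "inactivation")
        # ~7.6% of channels inactivated at -100 mV under the vehicle curve
        assert 1 - fit.availability(-100.0) == pytest.approx(0.0759, abs=1e-3)

    def test_non_sigmoidal_input_raises(self):
        v = np.arange(-120.0, -40.0, 5.0)
        with pytest.raises(FitError):
            fit_boltzmann(v, np.full_like(v, 0.8), "inactivation")


class TestMonoexp:
    def test_round_trip_and_tau(self):
        t = np.linspace(0, 100, 30)
        y = (1.0 - 0.4) * np.exp(-0.05 * t) + 0.4
        fit = fit_monoexp(t, y)
        assert fit.y0 == pytest.approx(1.0, rel=1e-6)
        assert fit.plateau == pytest.approx(0.4, rel=1e-6)
        assert fit.tau == pytest.approx(20.0, rel=1e-6)
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(fit.y0)

    def test_constant_series_unidentifiable(self):
        with pytest.raises(FitError):
            fit_monoexp(np.arange(5.0), np.ones(5))

    def test_unordered_time_rejected(self):
        with pytest.raises(FitError):
            fit_monoexp([0.0, 2.0, 1.0, 3.0], [1.0, 0.7, 0.8, 0.6])


class TestBiexp:
    def test_noiseless_round_trip(self):
        t = np.geomspace(1e-3, 10, 40)
        truth = BiexpFit(0.05, 1.0, 70.0, 40.0, 0.8, False, 0.0)
        fit = fit_biexp(t, truth.predict(t))
        assert fit.y0 == pytest.approx(0.05, abs=1e-6)
        assert fit.plateau == pytest.approx(1.0, rel=1e-6)
        assert fit.percent_fast == pytest.approx(70.0, rel=1e-4)
        assert fit.k_fast == pytest.approx(40.0, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.8, rel=1e-4)

    def test_span_identity_and_limits(self):
        fit = BiexpFit(0.1, 1.0, 30.0, 10.0, 0.5, False, 0.0)
        assert fit.span_fast + fit.span_slow == pytest.approx(fit.y0 - fit.plateau)
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(fit.y0)
        assert fit.predict(np.array([1e6]))[0] == pytest.approx(fit.plateau)

    def test_all_fast_reduces_to_single_exponential(self):
        t = np.geomspace(1e-3, 5, 50)
        mono = (0.0 - 1.0) * np.exp(-3.0 * t) + 1.0
        fit = fit_biexp(t, mono)
        assert fit.degenerate
        assert fit.predict(t) == pytest.approx(mono, abs=1e-6)

    def test_ordering_enforced(self):
        t = np.geomspace(1e-3, 10, 40)
        y = BiexpFit(0.0, 1.0, 40.0, 20.0, 0.5, False, 0.0).predict(t)
        fit = fit_biexp(t, y)
        assert fit.k_fast >= fit.k_slow


class TestIV:
    def test_linear_iv_zero_crossing(self):
        iv = [(v, 2.0 * (v - 68.0)) for v in range(-40, 90, 10)]
        assert estimate_reversal(iv) == pytest.approx(68.0)

    def test_ohmic_toy_model(self):
        iv = [IVRecord(v, 0.5 * (v - 65.0)) for v in range(-120, 80, 5)]
        assert estimate_reversal(iv) == pytest.approx(65.0)

    def test_no_sign_change_advises_nernst(self):
        iv = [(v, -abs(v) - 1.0) for v in range(-60, 0, 10)]
        with pytest.raises(FitError, match="nernst"):
            estimate_reversal(iv)

    def test_nernst_for_recording_solutions(self):
        # 145 mM out / 10 mM in at 22 C
        assert nernst_potential(145.0, 10.0, 22.0) == pytest.approx(68.0, abs=0.1)

    def test_conductance_transform(self):
        recs = conductance_from_iv([(-25.0, -1000.0), (0.0, 0.0)], e_na=68.0)
        assert recs[0].g == pytest.approx(1000.0 / 93.0)
        assert recs[1].g == 0.0

    def test_singularity_excluded_and_flagged(self):
        recs = conductance_from_iv([(67.5, 10.0), (-20.0, -500.0)], e_na=68.0)
        flagged = [r for r in recs if r.excluded]
        assert len(flagged) == 1 and flagged[0].v == 67.5 and flagged[0].g is None
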