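"""Analysis stages: QC, normalization, stage analyses, four-state fit."""

import numpy as np
import pandas as pd
import pytest

from navblock.analysis import (
    QCThresholds,
    analyze_activation,
    analyze_open_state_tau,
    analyze_recovery,
    analyze_ssi,
    apply_qc,
    build_concentration_response,
    fit_four_state,
    predict_equilibrium_inhibition,
    vehicle_normalize,
)
from navblock.curvefit import BiexpFit, FitError, HillFit, NoInhibition
from navblock.model import steady_state_availability, equilibrium_apparent_ic50
from navblock.protocols import build_protocol
from navblock.simulate import PEAK_COLUMNS, run_protocol


def _records(rows):
    df = pd.DataFrame(rows)
    for col in PEAK_COLUMNS:
        if col not in df:
            df[col] = np.nan
    return df[PEAK_COLUMNS]


class TestQC:
    def toy(self, cells):
        return _records(
            [
                dict(cell_id=f"c{i}", protocol="ssi", peak_pA=-p, rm_MOhm=rm, rs_MOhm=rs, conc_uM=0)
                for i, (rm, rs, p) in enumerate(cells)
            ]
        )

    def test_enumerated_criteria(self):
        table = self.toy([(600, 5, 800), (400, 5, 800), (600, 12, 800), (600, 5, 400), (700, 2, 900)])
        kept, log = apply_qc(table, QCThresholds())
        assert sorted(kept.cell_id.unique()) == ["c0", "c4"]
        assert set(zip(log.cell_id, log.criterion)) == {
            ("c1", "membrane_resistance"),
            ("c2", "series_resistance"),
            ("c3", "peak_magnitude"),
        }

    def test_boundary_values_excluded(self):
        # thresholds are strict inequalities
        kept_and_log = apply_qc(
            self.toy([(500, 10, 500), (501, 9.9, 501)]), QCThresholds()
        )
        kept, log = kept_and_log
        assert list(kept.cell_id.unique()) == ["c1"]
        assert set(log.cell_id) == {"c0"}
        assert len(log) == 3

    def test_empty_result_names_binding_criterion(self):
        with pytest.raises(FitError, match="membrane_resistance"):
            apply_qc(self.toy([(100, 5, 900), (200, 5, 900)]), QCThresholds())


class TestVehicleNormalize:
    T = np.arange(0.0, 100.0, 10.0)

    def test_identical_series_gives_zero(self):
        series = np.column_stack([self.T, np.exp(-0.01 * self.T)])
        out = vehicle_normalize(series, series)
        assert np.allclose(out.inhibition, 0.0)

    def test_constant_factor(self):
        veh = np.column_stack([self.T, np.ones_like(self.T)])
        drug = np.column_stack([self.T, np.full_like(self.T, 0.5)])
        assert np.allclose(vehicle_normalize(drug, veh).inhibition, 0.5)

    def test_rundown_corrected(self):
        veh = np.column_stack([[0.0], [0.9]])
        drug = np.column_stack([[0.0], [0.45]])
        assert vehicle_normalize(drug, veh).inhibition.iloc[0] == pytest.approx(0.5)

    def test_vehicle_reaching_zero_rejected(self):
        veh = np.column_stack([self.T, np.linspace(1, 0, len(self.T))])
        drug = np.column_stack([self.T, np.ones_like(self.T)])
        with pytest.raises(ValueError):
            vehicle_normalize(drug, veh)

    def test_out_of_range_clamped_and_flagged(self):
        veh = np.column_stack([[0.0], [1.0]])
        drug = np.column_stack([[0.0], [2.0]])
        out = vehicle_normalize(drug, veh)
        assert out.inhibition.iloc[0] == -0.2 and out.clamped.iloc[0]


class TestPredictInhibition:
    def test_limits(self):
        assert predict_equilibrium_inhibition(10.0, 0.0) == 0.0
        assert predict_equilibrium_inhibition(10.0, 1e9) == pytest.approx(1.0, abs=1e-7)

    def test_printed_consistency(self):
        assert predict_equilibrium_inhibition(96.5, 30.0) == pytest.approx(0.237, abs=5e-4)


class TestFourState:
    def availability(self, v):
        return 1.0 / (1.0 + np.exp((v + 80.0) / 8.0))

    def test_exact_generation_recovers_constants(self, gating, drug):
        volts = (-110.0, -100.0, -90.0, -80.0)
        ic50 = {
            v: equilibrium_apparent_ic50(drug, steady_state_availability(gating, v))
            for v in volts
        }
        fit = fit_four_state(ic50, self.availability)
        assert fit.k_r == pytest.approx(108.0, rel=1e-6)
        assert fit.k_i == pytest.approx(3.6, rel=1e-6)
        assert fit.fold_preference == pytest.approx(30.0, rel=1e-6)
        assert fit.residual_norm < 1e-8 and not fit.boundary

    def test_identical_ic50s_collapse_to_single_constant(self):
        fit = fit_four_state({-110.0: 12.0, -90.0: 12.0, -80.0: 12.0}, self.availability)
        assert fit.k_r == pytest.approx(12.0, rel=1e-6)
        assert fit.k_i == pytest.approx(12.0, rel=1e-6)

    def test_identical_availability_unidentifiable(self):
        with pytest.raises(FitError):
            fit_four_state({-110.0: 60.0, -100.0: 30.0}, lambda v: 0.5)

    def test_too_few_voltages(self):
        with pytest.raises(FitError):
            fit_four_state({-80.0: 7.0}, self.availability)

    def test_inverted_voltage_dependence_hits_boundary(self):
        # potency decreasing with depolarization cannot be explained with
        # K_I < K_R; one reciprocal constant pins at zero.
        fit = fit_four_state({-110.0: 5.0, -80.0: 500.0}, self.availability)
        assert fit.boundary


class TestConcentrationResponse:
    def synthetic_records(self):
        """Minimal two-interval train: vehicle stable, drug cells inhibited."""
        rows = []
        inhib = {("d0", -100.0): 0.4, ("d1", -100.0): 0.6, ("d0", -80.0): 0.7, ("d1", -80.0): 0.9}
        for cell, conc in [("v0", 0.0), ("v1", 0.0), ("d0", 10.0), ("d1", 10.0)]:
            for ii, hp in enumerate((-100.0, -80.0)):
                for pulse in (1, 176, 177, 178, 179, 180):
                    peak = -1000.0
                    if conc and pulse > 1:
                        peak *= 1.0 - inhib[(cell, hp)]
                    rows.append(
                        dict(
                            cell_id=cell,
                            protocol="state_dependence",
                            holding_mV=hp,
                            pulse_number=pulse,
                            interval_index=ii,
                            conc_uM=conc,
                            peak_pA=peak,
                        )
                    )
        return _records(rows)

    def test_mean_pooling_across_cells(self):
        cr = build_concentration_response(self.synthetic_records())
        last = cr[-100.0]["last"]
        assert last.concentrations == (10.0,)
        assert last.inhibition[0] == pytest.approx(0.5)
        assert last.n == (2,)
        assert cr[-80.0]["last"].inhibition[0] == pytest.approx(0.8)

    def test_first_pulse_flagged_no_inhibition(self):
        cr = build_concentration_response(self.synthetic_records())
        assert isinstance(cr[-100.0]["first"].fit, NoInhibition)

    def test_vehicle_arm_required(self):
        rec = self.synthetic_records()
        with pytest.raises(ValueError):
            build_concentration_response(rec[rec.conc_uM > 0])


class TestActivationAnalysis:
    def test_toy_current_density_and_ratio(self):
        rows = []
        for cell, conc, scale in [("v", 0.0, 1.0), ("d", 30.0, 0.5)]:
            for v in range(-120, 30, 5):
                g = 1.0 / (1.0 + np.exp((-30.0 - v) / 7.0))
                rows.append(
                    dict(
                        cell_id=cell,
                        protocol="activation",
                        step_mV=float(v),
                        peak_pA=scale * 15.0 * g * (v - 68.0),
                        conc_uM=conc,
                        cap_pF=15.0,
                    )
                )
        df = _records(rows)
        out = analyze_activation(df, e_na=68.0)
        s = out.summary.set_index("conc_uM")
        assert s.loc[30.0, "gmax_ratio"] == pytest.approx(0.5, rel=1e-6)
        assert abs(s.loc[30.0, "delta_v_half"]) < 0.1
        # density = largest-magnitude peak over capacitance, sign restored
        expected = df[df.conc_uM == 0].peak_pA.abs().max() / 15.0
        assert s.loc[0.0, "peak_density_pA_pF"] == pytest.approx(-expected, rel=1e-6)

    def test_nernst_fallback_when_iv_all_inward(self, cell, gating, drug):
        rec, _ = run_protocol(cell, gating, drug, build_protocol("activation"), 0.0)
        rec["cell_id"] = "c"
        out = analyze_activation(rec)
        assert out.e_na == pytest.approx(68.0, abs=0.1)


class TestSSIAnalysis:
    def test_vehicle_round_trip_recovers_boltzmann(self, cell, gating, drug):
        rec, _ = run_protocol(cell, gating, drug, build_protocol("ssi"), 0.0)
        rec["cell_id"] = "c"
        out = analyze_ssi(rec)
        fit = out.fits[0.0]
        assert fit.v_half == pytest.approx(gating.ssi_v_half, abs=1.0)
        assert fit.k == pytest.approx(gating.ssi_slope, abs=0.5)

    def test_two_vehicle_arms_give_zero_shift(self, cell, gating, drug):
        rec, _ = run_protocol(cell, gating, drug, build_protocol("ssi"), 0.0)
        a, b = rec.copy(), rec.copy()
        a["cell_id"], b["cell_id"] = "a", "b"
        b["conc_uM"] = 0.0
        out = analyze_ssi(pd.concat([a, b], ignore_index=True))
        assert (out.summary["delta_v_half"] == 0).all()

    def test_drug_hyperpolarizes_concentration_dependently(self, cell, gating, drug):
        frames = []
        for conc in (0.0, 4.0, 30.0):
            rec, _ = run_protocol(cell, gating, drug, build_protocol("ssi"), conc, init="full")
            rec["cell_id"] = f"c{conc}"
            frames.append(rec)
        s = analyze_ssi(pd.concat(frames, ignore_index=True)).summary.set_index("conc_uM")
        assert s.loc[30.0, "delta_v_half"] < s.loc[4.0, "delta_v_half"] < 0

    def test_too_few_voltages(self):
        rec = _records(
            [
                dict(cell_id="c", protocol="ssi", step_mV=v, peak_pA=-500.0, conc_uM=0.0)
                for v in (-120.0, -80.0, -40.0)
            ]
        )
        with pytest.raises(FitError):
            analyze_ssi(rec)


class TestRecoveryAnalysis:
    def test_known_biexponential_recovered(self):
        truth = BiexpFit(0.05, 1.0, 60.0, 500.0, 1.0, False, 0.0)
        intervals = np.array([1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 3000, 10000], float)
        rows = []
        for cell in ("a", "b"):
            for dt in intervals:
                avail = truth.predict(np.array([dt * 1e-3]))[0]
                rows.append(
                    dict(cell_id=cell, protocol="recovery", prepulse_ms=20.0,
                         recovery_ms=dt, pulse_number=np.nan, peak_pA=-1000.0 * avail,
                         conc_uM=0.0)
                )
                rows.append(
                    dict(cell_id=cell, protocol="recovery", prepulse_ms=20.0,
                         recovery_ms=dt, pulse_number=0, peak_pA=-1000.0, conc_uM=0.0)
                )
        out = analyze_recovery(_records(rows))
        fit = out.fits[(0.0, 20.0)]
        assert fit.k_fast == pytest.approx(500.0, rel=1e-3)
        assert fit.k_slow == pytest.approx(1.0, rel=1e-3)
        assert fit.percent_fast == pytest.approx(60.0, rel=1e-3)
        assert np.isfinite(out.summary.t_half_s.iloc[0])

    def test_reference_rows_required(self):
        rec = _records(
            [dict(cell_id="c", protocol="recovery", prepulse_ms=20.0, recovery_ms=1.0,
                  pulse_number=np.nan, peak_pA=-500.0, conc_uM=0.0)]
        )
        with pytest.raises(ValueError):
            analyze_recovery(rec)


@pytest.fixture(scope="module")
def peak_traces(cell, gating, drug):
    out = {}
    for conc in (0.0, 30.0):
        rec, traces = run_protocol(
            cell, gating, drug, build_protocol("activation"), conc,
            init="full", record_traces=True,
        )
        idx = int(rec.reset_index(drop=True).peak_pA.idxmin())
        out[conc] = [traces[idx]]
    return out


class TestOpenStateTau:
    def test_matches_gating_eigenvalue(self, peak_traces, gating, drug):
        from navblock.model import rate_matrix

        table = analyze_open_state_tau(peak_traces).set_index("conc_uM")
        w = np.linalg.eigvals(rate_matrix(gating, drug, -25.0, 0.0)[:4, :4])
        taus = np.sort(-1.0 / w.real[np.abs(w.real) > 1e-6])
        decay_tau = taus[1]  # between the fast activation and slow modes
        assert table.loc[0.0, "tau_ms_mean"] == pytest.approx(decay_tau, rel=0.05)

    def test_no_open_state_binding_leaves_tau_unchanged(self, peak_traces):
        table = analyze_open_state_tau(peak_traces).set_index("conc_uM")
        assert table.loc[30.0, "tau_ms_mean"] == pytest.approx(
            table.loc[0.0, "tau_ms_mean"], rel=0.02
        )

    def test_monotonically_rising_trace_rejected(self):
        tr = pd.DataFrame({"time_ms": np.arange(0, 5, 0.04)})
        tr["current_pA"] = -tr.time_ms
        with pytest.raises(FitError):
            analyze_open_state_tau({0.0: [tr]})
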