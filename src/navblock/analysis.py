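"""Analysis stages for peak-current tables from state-dependent block assays.

Stages mirror an automated patch-clamp workflow: cell-level quality
control, vehicle normalization (correcting compound-independent rundown),
activation/conductance analysis, steady-state inactivation, recovery from
inactivation, block-equilibration kinetics, use-dependent
concentration-response construction, and the four-state (resting vs
inactivated affinity) fit that resolves K_R and K_I from the voltage
dependence of the apparent IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, nnls

from .curvefit import (
    BoltzmannFit,
    BiexpFit,
    ExpFit,
    FitError,
    HillFit,
    IVRecord,
    NoInhibition,
    conductance_from_iv,
    estimate_reversal,
    fit_biexp,
    fit_boltzmann,
    fit_hill,
    fit_monoexp,
    nernst_potential,
)

__all__ = [
    "QCThresholds",
    "apply_qc",
    "vehicle_normalize",
    "ConcentrationResponse",
    "build_concentration_response",
    "StateDependenceFit",
    "fit_four_state",
    "use_dependent_availability",
    "predict_equilibrium_inhibition",
    "analyze_activation",
    "analyze_ssi",
    "analyze_recovery",
    "analyze_block_kinetics",
    "analyze_open_state_tau",
]


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level quality filters (strict inequalities)."""

    min_rm_MOhm: float = 500.0
    max_rs_MOhm: float = 10.0
    min_peak_pA: float = 500.0

    def __post_init__(self) -> None:
        if min(self.min_rm_MOhm, self.max_rs_MOhm, self.min_peak_pA) <= 0:
            raise ValueError("QC thresholds must be positive")


def apply_qc(
    records: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove whole cells failing any quality criterion.

    A cell passes when membrane resistance > min_rm, series resistance
    < max_rs and maximal peak current magnitude > min_peak (all strict).
    Returns the filtered table and an exclusion log with one row per
    (cell, failed criterion).
    """
    thresholds = thresholds or QCThresholds()
    log_rows = []
    keep_cells = []
    for cell_id, grp in records.groupby("cell_id", sort=True):
        rm = float(grp["rm_MOhm"].iloc[0])
        rs = float(grp["rs_MOhm"].iloc[0])
        peak = float(grp["peak_pA"].abs().max())
        failed = []
        if not rm > thresholds.min_rm_MOhm:
            failed.append(("membrane_resistance", rm))
        if not rs < thresholds.max_rs_MOhm:
            failed.append(("series_resistance", rs))
        if not peak > thresholds.min_peak_pA:
            failed.append(("peak_magnitude", peak))
        if failed:
            log_rows.extend(
                dict(cell_id=cell_id, criterion=c, value=v) for c, v in failed
            )
        else:
            keep_cells.append(cell_id)
    out = records[records["cell_id"].isin(keep_cells)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["cell_id", "criterion", "value"])
    if out.empty:
        top = log["criterion"].mode().iloc[0] if len(log) else "unknown"
        raise FitError(f"no cells survive QC (binding criterion: {top})")
    return out, log


# ---------------------------------------------------------------------------
# vehicle normalization


def vehicle_normalize(
    drug_series: pd.DataFrame | Sequence[tuple[float, float]],
    vehicle_series: pd.DataFrame | Sequence[tuple[float, float]],
    clamp: tuple[float, float] = (-0.2, 1.2),
) -> pd.DataFrame:
    """Inhibition fraction over time, corrected by the vehicle time course.

    Both inputs are ``(time_s, normalized_current)`` series already scaled
    to their own baselines.  The vehicle series is interpolated onto the
    drug time grid and ``inhibition(t) = 1 - drug(t) / vehicle(t)``;
    values outside ``clamp`` are clamped and flagged.
    """

    def arr(series) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(series, pd.DataFrame):
            a = series.to_numpy(dtype=float)
        else:
            a = np.asarray(series, dtype=float)
        return a[:, 0], a[:, 1]

    td, yd = arr(drug_series)
    tv, yv = arr(vehicle_series)
    if np.any(yv <= 0):
        raise ValueError("vehicle series reaches zero; cannot normalize")
    vi = np.interp(td, tv, yv)
    inhib = 1.0 - yd / vi
    clamped = (inhib < clamp[0]) | (inhib > clamp[1])
    return pd.DataFrame(
        {
            "time_s": td,
            "inhibition": np.clip(inhib, clamp[0], clamp[1]),
            "clamped": clamped,
        }
    )


# ---------------------------------------------------------------------------
# use-dependent concentration response


@dataclass(frozen=True)
class ConcentrationResponse:
    """Pooled inhibition vs concentration at one holding potential."""

    holding_mV: float
    pulse: str  # "first" | "last"
    concentrations: tuple[float, ...]
    inhibition: tuple[float, ...]  # pooled mean per concentration
    sem: tuple[float, ...]
    n: tuple[int, ...]
    fit: HillFit | NoInhibition | None  # None when too few concentrations to fit

    @property
    def ic50(self) -> float | None:
        return self.fit.ic50 if isinstance(self.fit, HillFit) else None


def _hill_with_slope_rule(
    conc: np.ndarray,
    y: np.ndarray,
    fix_slope: float | None,
    rel_stderr_limit: float,
    no_inhibition_threshold: float,
) -> HillFit | NoInhibition:
    """Free-slope fit, falling back to a fixed unit slope when the slope is
    poorly determined (relative standard error above the limit)."""
    if fix_slope is not None:
        return fit_hill(conc, y, fix_slope, no_inhibition_threshold=no_inhibition_threshold)
    fit = fit_hill(conc, y, no_inhibition_threshold=no_inhibition_threshold)
    if isinstance(fit, HillFit):
        rel = fit.hill_stderr / abs(fit.hill) if fit.hill else np.inf
        if not np.isfinite(rel) or rel > rel_stderr_limit:
            fit = fit_hill(conc, y, 1.0, no_inhibition_threshold=no_inhibition_threshold)
    return fit


def build_concentration_response(
    sd_records: pd.DataFrame,
    *,
    no_inhibition_threshold: float = 0.1,
    fix_slope: float | None = None,
    slope_rel_stderr_limit: float = 0.5,
    last_pulse_window: int = 5,
) -> dict[float, dict[str, ConcentrationResponse]]:
    """First- and last-pulse concentration-response curves per holding potential.

    Each cell is normalized to its own first pulse of the first interval;
    vehicle cells provide the compound-independent reference at every
    (interval, pulse), and inhibition is pooled across the cells of each
    concentration (one concentration per cell).  The end-of-train
    ("last pulse") response is averaged over the final ``last_pulse_window``
    pulses — all at equilibrium by construction of the 180-pulse train —
    to suppress single-sweep peak noise.  Hill fits follow the slope rule:
    free slope unless poorly determined, then fixed to 1.
    """
    rec = sd_records[sd_records["protocol"] == "state_dependence"]
    if rec.empty:
        raise ValueError("no state-dependence records")
    last_pulse = int(rec["pulse_number"].max())
    first_interval = int(rec["interval_index"].min())
    window = [last_pulse - i for i in range(max(1, last_pulse_window))]
    window = [p for p in window if p > 1]

    sel = rec[rec["pulse_number"].isin([1] + window)].copy()

    # per-cell normalization to its own first pulse of the first interval
    baselines = (
        rec[(rec["pulse_number"] == 1) & (rec["interval_index"] == first_interval)]
        .set_index("cell_id")["peak_pA"]
    )
    missing = set(sel["cell_id"]) - set(baselines.index)
    if missing:
        raise ValueError(f"cells missing the reference pulse: {sorted(missing)[:3]}")
    sel["ratio"] = sel["peak_pA"].to_numpy() / baselines.loc[sel["cell_id"]].to_numpy()
    sel["pulse_label"] = np.where(sel["pulse_number"] == 1, "first", "last")

    veh = sel[sel["conc_uM"] == 0]
    if veh.empty:
        raise ValueError("vehicle arm (0 uM) required for normalization")
    veh_mean = veh.groupby(["holding_mV", "pulse_label"])["ratio"].mean()

    out: dict[float, dict[str, ConcentrationResponse]] = {}
    for hp, grp_hp in sel.groupby("holding_mV"):
        out[float(hp)] = {}
        for pulse_label, pulse_no in (("first", 1), ("last", last_pulse)):
            grp = grp_hp[grp_hp["pulse_label"] == pulse_label]
            if grp.empty:
                raise ValueError(f"missing pulse {pulse_no} at {hp} mV")
            ref = veh_mean.loc[(hp, pulse_label)]
            drug = grp[grp["conc_uM"] > 0].copy()
            cell_ratio = (
                drug.groupby(["conc_uM", "cell_id"])["ratio"].mean().reset_index()
            )
            cell_ratio["inhibition"] = 1.0 - cell_ratio["ratio"] / ref
            pooled = cell_ratio.groupby("conc_uM")["inhibition"].agg(["mean", "sem", "count"])
            conc = pooled.index.to_numpy(dtype=float)
            y = np.clip(pooled["mean"].to_numpy(), -0.2, 1.2)
            try:
                fit = _hill_with_slope_rule(
                    conc, y, fix_slope, slope_rel_stderr_limit, no_inhibition_threshold
                )
            except FitError:
                fit = None  # e.g. a single tested concentration: pooled only
            out[float(hp)][pulse_label] = ConcentrationResponse(
                holding_mV=float(hp),
                pulse=pulse_label,
                concentrations=tuple(conc),
                inhibition=tuple(y),
                sem=tuple(pooled["sem"].fillna(0.0)),
                n=tuple(int(c) for c in pooled["count"]),
                fit=fit,
            )
    return out


# ---------------------------------------------------------------------------
# four-state (two-affinity) fit


AvailabilitySource = BoltzmannFit | Mapping[float, float] | Callable[[float], float]


def _availability_fn(source: AvailabilitySource) -> Callable[[float], float]:
    if isinstance(source, BoltzmannFit):
        return source.availability
    if isinstance(source, Mapping):
        table = {float(k): float(v) for k, v in source.items()}
        return lambda v: table[float(v)]
    return source


@dataclass(frozen=True)
class StateDependenceFit:
    """Resting / inactivated dissociation constants from apparent IC50s.

    The reciprocal apparent IC50 is modelled as the availability-weighted
    sum ``1/IC50(V) = h(V)/K_R + (1 - h(V))/K_I``; with availability fixed
    this is linear in (1/K_R, 1/K_I) and solved by non-negative least
    squares.
    """

    k_r: float  # uM
    k_i: float  # uM
    voltages: tuple[float, ...]
    availabilities: tuple[float, ...]
    residual_norm: float
    boundary: bool  # a coefficient pinned at zero
    ic50_ratio: float  # max/min of the measured apparent IC50s

    @property
    def fold_preference(self) -> float:
        return self.k_r / self.k_i


def fit_four_state(
    ic50_by_voltage: Mapping[float, float],
    availability: AvailabilitySource,
    duty_fraction: float = 0.0,
    weighting: str = "relative",
) -> StateDependenceFit:
    """Resolve K_R and K_I from the voltage dependence of the apparent IC50.

    Parameters
    ----------
    ic50_by_voltage : mapping mV -> uM
        Apparent IC50 per holding potential (voltages flagged as showing
        no inhibition should be omitted by the caller).
    availability : BoltzmannFit, mapping or callable
        Non-inactivated fraction h(V), typically the vehicle steady-state
        inactivation Boltzmann.
    duty_fraction : float
        Fraction of each pulse-train cycle spent depolarized (pulse width
        over period); reduces the availability entering the model to
        ``(1 - duty_fraction) * h(V)``.  Zero (default) disables the
        correction.
    weighting : {"relative", "none"}
        ``relative`` scales each 1/IC50 residual by its own magnitude
        (equal fractional weight for apparent potencies spanning decades);
        ``none`` fits the reciprocals on the absolute scale.  Either way
        the problem stays linear and is solved with a non-negativity
        constraint.
    """
    if not 0.0 <= duty_fraction < 1.0:
        raise ValueError("duty_fraction must be in [0, 1)")
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")
    items = sorted((float(v), float(ic)) for v, ic in ic50_by_voltage.items())
    if len(items) < 2:
        raise FitError("need apparent IC50s at >= 2 voltages")
    if any(ic <= 0 or not math.isfinite(ic) for _, ic in items):
        raise FitError("apparent IC50s must be finite and positive")
    h_fn = _availability_fn(availability)
    volts = np.array([v for v, _ in items])
    ic50s = np.array([ic for _, ic in items])
    h = np.array([h_fn(v) for v in volts]) * (1.0 - duty_fraction)
    if np.ptp(h) < 1e-6:
        raise FitError("availability identical at all voltages: K_R, K_I unidentifiable")
    A = np.column_stack([h, 1.0 - h])
    b = 1.0 / ic50s
    if weighting == "relative":
        w = 1.0 / b
        coef, rnorm = nnls(A * w[:, None], b * w)
    else:
        coef, rnorm = nnls(A, b)
    boundary = bool(np.any(coef <= 0))
    with np.errstate(divide="ignore"):
        k_r = float(1.0 / coef[0]) if coef[0] > 0 else float("inf")
        k_i = float(1.0 / coef[1]) if coef[1] > 0 else float("inf")
    return StateDependenceFit(
        k_r=k_r,
        k_i=k_i,
        voltages=tuple(volts),
        availabilities=tuple(h),
        residual_norm=float(rnorm),
        boundary=boundary,
        ic50_ratio=float(ic50s.max() / ic50s.min()),
    )


def use_dependent_availability(
    sd_records: pd.DataFrame, reference_availability: float | BoltzmannFit
) -> dict[float, float]:
    """Availability per holding potential measured from vehicle pulse trains.

    The vehicle current at the last pulse of each interval, relative to the
    very first pulse (delivered from the near-rested first holding
    potential), estimates the availability the pulse train itself sets up.
    ``reference_availability`` anchors the absolute scale at the first
    holding potential (a value or an inactivation Boltzmann).
    """
    veh = sd_records[
        (sd_records["protocol"] == "state_dependence") & (sd_records["conc_uM"] == 0)
    ]
    if veh.empty:
        raise ValueError("no vehicle state-dependence records")
    last_pulse = int(veh["pulse_number"].max())
    first_interval = int(veh["interval_index"].min())
    first_hp = float(veh.loc[veh["interval_index"] == first_interval, "holding_mV"].iloc[0])
    if isinstance(reference_availability, BoltzmannFit):
        h_ref = reference_availability.availability(first_hp)
    else:
        h_ref = float(reference_availability)
    base = veh[(veh["pulse_number"] == 1) & (veh["interval_index"] == first_interval)]
    base_mean = base.groupby("cell_id")["peak_pA"].first()
    lastp = veh[veh["pulse_number"] == last_pulse].copy()
    lastp["ratio"] = lastp["peak_pA"].to_numpy() / base_mean.loc[lastp["cell_id"]].to_numpy()
    curve = lastp.groupby("holding_mV")["ratio"].mean()
    return {float(v): float(min(h_ref * r, 1.0)) for v, r in curve.items()}


def predict_equilibrium_inhibition(ic50: float, conc: float) -> float:
    """Unit-slope Hill inhibition ``conc / (conc + IC50)``."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if conc < 0:
        raise ValueError("conc must be >= 0")
    return conc / (conc + ic50)


# ---------------------------------------------------------------------------
# activation / conductance


@dataclass(frozen=True)
class ActivationAnalysis:
    e_na: float
    summary: pd.DataFrame  # one row per concentration
    gv: pd.DataFrame  # pooled conductance by voltage per concentration
    fits: dict[float, BoltzmannFit] = field(default_factory=dict)


def analyze_activation(
    records: pd.DataFrame, e_na: float | str = "auto"
) -> ActivationAnalysis:
    """Conductance-voltage analysis of activation-protocol records.

    Per concentration: chord conductance from the pooled IV (Nernst-based
    reversal when the IV lacks an outward limb), maximal conductance,
    current density, and the Boltzmann fit of the normalized G-V.  The
    summary reports maximal-conductance ratio and activation midpoint
    shift relative to vehicle when a vehicle arm is present.
    """
    rec = records[records["protocol"] == "activation"]
    if rec.empty:
        raise ValueError("no activation records")

    if e_na == "auto":
        mean_iv = rec.groupby("step_mV")["peak_pA"].mean()
        try:
            e_na_val = estimate_reversal(list(zip(mean_iv.index, mean_iv.to_numpy())))
        except FitError:
            # IV families truncated below the reversal potential: fall back
            # to the Nernst potential of the recording solutions (145/10 mM Na).
            e_na_val = nernst_potential(145.0, 10.0)
    else:
        e_na_val = float(e_na)

    gv_rows = []
    summaries = []
    fits: dict[float, BoltzmannFit] = {}
    for conc, grp in rec.groupby("conc_uM"):
        gmaxes, densities = [], []
        for _, cell_grp in grp.groupby("cell_id"):
            iv = conductance_from_iv(
                list(zip(cell_grp["step_mV"], cell_grp["peak_pA"])), e_na_val
            )
            g = np.array([r.g for r in iv if not r.excluded])
            gmaxes.append(g.max())
            densities.append(float(cell_grp["peak_pA"].abs().max() / cell_grp["cap_pF"].iloc[0]))
        pooled_iv = grp.groupby("step_mV")["peak_pA"].mean()
        iv = conductance_from_iv(list(zip(pooled_iv.index, pooled_iv.to_numpy())), e_na_val)
        v = np.array([r.v for r in iv if not r.excluded])
        g = np.array([r.g for r in iv if not r.excluded])
        gnorm = g / g.max()
        fit = fit_boltzmann(v, gnorm, direction="activation")
        fits[float(conc)] = fit
        for vj, gj, gn in zip(v, g, gnorm):
            gv_rows.append(dict(conc_uM=conc, step_mV=vj, g_nS=gj, g_norm=gn))
        gmaxes = np.asarray(gmaxes)
        densities = np.asarray(densities)
        summaries.append(
            dict(
                conc_uM=float(conc),
                n_cells=len(gmaxes),
                gmax_nS=gmaxes.mean(),
                gmax_sem=gmaxes.std(ddof=1) / math.sqrt(len(gmaxes)) if len(gmaxes) > 1 else 0.0,
                peak_density_pA_pF=-densities.mean(),
                v_half=fit.v_half,
                k=fit.k,
                peak_voltage_mV=float(pooled_iv.idxmin()),
            )
        )
    summary = pd.DataFrame(summaries).sort_values("conc_uM").reset_index(drop=True)
    if (summary["conc_uM"] == 0).any():
        veh = summary[summary["conc_uM"] == 0].iloc[0]
        summary["gmax_ratio"] = summary["gmax_nS"] / veh["gmax_nS"]
        summary["delta_v_half"] = summary["v_half"] - veh["v_half"]
    return ActivationAnalysis(
        e_na=float(e_na_val), summary=summary, gv=pd.DataFrame(gv_rows), fits=fits
    )


# ---------------------------------------------------------------------------
# steady-state inactivation


@dataclass(frozen=True)
class SSIAnalysis:
    prepulse_ms: float
    summary: pd.DataFrame  # conc, v_half, k, delta_v_half
    fits: dict[float, BoltzmannFit]
    curves: pd.DataFrame  # pooled availability per (conc, prepulse voltage)


def analyze_ssi(records: pd.DataFrame, prepulse_duration: float | None = None) -> SSIAnalysis:
    """Boltzmann analysis of steady-state (fast or slow) inactivation.

    Test-pulse currents are normalized to each cell's maximum, pooled per
    concentration, and fitted with the inactivation Boltzmann; the summary
    lists midpoints and shifts relative to vehicle.
    """
    rec = records[records["protocol"].isin(["ssi", "slow_ssi"])]
    rec = rec[rec["pulse_number"].isna() | (rec["pulse_number"] != 0)]
    if prepulse_duration is not None:
        rec = rec[rec["prepulse_ms"] == prepulse_duration]
    if rec.empty:
        raise ValueError("no steady-state inactivation records")
    if rec["step_mV"].nunique() < 4:
        raise FitError("need >= 4 prepulse voltages")
    prepulse_ms = float(rec["prepulse_ms"].iloc[0])

    rec = rec.copy()
    cell_max = rec.groupby("cell_id")["peak_pA"].transform(lambda s: s.abs().max())
    rec["availability"] = rec["peak_pA"].abs() / cell_max

    fits: dict[float, BoltzmannFit] = {}
    rows = []
    curve_frames = []
    for conc, grp in rec.groupby("conc_uM"):
        pooled = grp.groupby("step_mV")["availability"].agg(["mean", "sem", "std"])
        fit = fit_boltzmann(pooled.index.to_numpy(), pooled["mean"].to_numpy(), "inactivation")
        fits[float(conc)] = fit
        rows.append(dict(conc_uM=float(conc), v_half=fit.v_half, k=fit.k))
        cf = pooled.reset_index().rename(
            columns={"mean": "availability", "sem": "availability_sem", "std": "availability_sd"}
        )
        cf.insert(0, "conc_uM", float(conc))
        curve_frames.append(cf)
    summary = pd.DataFrame(rows).sort_values("conc_uM").reset_index(drop=True)
    if (summary["conc_uM"] == 0).any():
        veh = summary.loc[summary["conc_uM"] == 0, "v_half"].iloc[0]
        summary["delta_v_half"] = summary["v_half"] - veh
    return SSIAnalysis(
        prepulse_ms=prepulse_ms,
        summary=summary,
        fits=fits,
        curves=pd.concat(curve_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# recovery from inactivation


@dataclass(frozen=True)
class RecoveryAnalysis:
    summary: pd.DataFrame  # conc, prepulse_ms, biexp params, t_half_s
    fits: dict[tuple[float, float], BiexpFit]
    curves: pd.DataFrame


def _half_recovery_time(fit: BiexpFit, t_max: float) -> float:
    target = fit.y0 + 0.5 * (fit.plateau - fit.y0)

    def f(t: float) -> float:
        return float(fit.predict(np.array([t]))[0] - target)

    lo, hi = 1e-7, t_max * 10
    if f(lo) * f(hi) > 0:  # pragma: no cover - pathological fit
        return float("nan")
    return float(brentq(f, lo, hi))


def analyze_recovery(records: pd.DataFrame) -> RecoveryAnalysis:
    """Bi-exponential recovery-from-inactivation analysis.

    Availability at each recovery interval is the test-pulse peak divided
    by the conditioning-prepulse peak of the same sweep (per cell), pooled
    per (concentration, prepulse duration) and fitted against the interval
    in seconds; reports component rates and the time to half recovery.
    """
    rec = records[records["protocol"] == "recovery"].copy()
    if rec.empty:
        raise ValueError("no recovery records")
    tests = rec[rec["pulse_number"].isna()]
    refs = rec[rec["pulse_number"] == 0]
    if refs.empty:
        raise ValueError("recovery records lack the conditioning-prepulse reference rows")
    ref_key = ["cell_id", "prepulse_ms", "recovery_ms"]
    merged = tests.merge(
        refs[ref_key + ["peak_pA"]], on=ref_key, suffixes=("", "_ref")
    )
    merged["availability"] = merged["peak_pA"] / merged["peak_pA_ref"]

    fits: dict[tuple[float, float], BiexpFit] = {}
    rows, curve_frames = [], []
    for (conc, pp), grp in merged.groupby(["conc_uM", "prepulse_ms"]):
        pooled = grp.groupby("recovery_ms")["availability"].agg(["mean", "sem"]).reset_index()
        if not pooled["recovery_ms"].is_monotonic_increasing:
            raise ValueError("recovery intervals must be ordered")
        t_s = pooled["recovery_ms"].to_numpy() * 1e-3
        y = pooled["mean"].to_numpy()
        fit = fit_biexp(t_s, y)
        fits[(float(conc), float(pp))] = fit
        rows.append(
            dict(
                conc_uM=float(conc),
                prepulse_ms=float(pp),
                y0=fit.y0,
                plateau=fit.plateau,
                percent_fast=fit.percent_fast,
                tau_fast_s=fit.tau_fast,
                tau_slow_s=fit.tau_slow,
                t_half_s=_half_recovery_time(fit, float(t_s.max())),
                degenerate=fit.degenerate,
            )
        )
        pooled.insert(0, "prepulse_ms", float(pp))
        pooled.insert(0, "conc_uM", float(conc))
        curve_frames.append(pooled)
    summary = pd.DataFrame(rows).sort_values(["prepulse_ms", "conc_uM"]).reset_index(drop=True)
    return RecoveryAnalysis(
        summary=summary, fits=fits, curves=pd.concat(curve_frames, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# kinetics of block equilibration


@dataclass(frozen=True)
class KineticsAnalysis:
    summary: pd.DataFrame  # conc, holding_mV, tau_s, final_inhibition, fitted
    fits: dict[tuple[float, float], ExpFit]
    curves: pd.DataFrame


def analyze_block_kinetics(
    records: pd.DataFrame,
    vehicle: pd.DataFrame | None = None,
    *,
    no_fit_threshold: float = 0.05,
) -> KineticsAnalysis:
    """Mono-exponential equilibration time constants (tau_observed).

    Peak currents from the pulse-train kinetics assay are normalized per
    cell to the first pulse, averaged per (concentration, holding
    potential), vehicle-corrected, and the inhibition time course is
    fitted with a single exponential.  Conditions whose final inhibition
    (mean of the last three points) stays below ``no_fit_threshold`` are
    flagged instead of fitted.
    """
    rec = records[records["protocol"] == "kinetics"].copy()
    if rec.empty:
        raise ValueError("no kinetics records")
    if vehicle is not None:
        veh = vehicle[vehicle["protocol"] == "kinetics"].copy()
    else:
        veh = rec[rec["conc_uM"] == 0].copy()
    if veh.empty:
        raise ValueError("vehicle kinetics records required")

    def mean_series(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        base = df[df["pulse_number"] == 1].set_index("cell_id")["peak_pA"]
        df["norm"] = df["peak_pA"].to_numpy() / base.loc[df["cell_id"]].to_numpy()
        return df.groupby("elapsed_s")["norm"].mean().reset_index()

    fits: dict[tuple[float, float], ExpFit] = {}
    rows, curve_frames = [], []
    for (conc, hp), grp in rec[rec["conc_uM"] > 0].groupby(["conc_uM", "holding_mV"]):
        veh_hp = veh[veh["holding_mV"] == hp]
        if veh_hp.empty:
            raise ValueError(f"no vehicle kinetics at {hp} mV")
        drug_series = mean_series(grp)
        veh_series = mean_series(veh_hp)
        inhib = vehicle_normalize(
            drug_series[["elapsed_s", "norm"]], veh_series[["elapsed_s", "norm"]]
        )
        final = float(inhib["inhibition"].tail(3).mean())
        fitted = final >= no_fit_threshold
        tau = np.nan
        if fitted:
            # fit the surviving current fraction (decaying form)
            fit = fit_monoexp(inhib["time_s"].to_numpy(), 1.0 - inhib["inhibition"].to_numpy())
            fits[(float(conc), float(hp))] = fit
            tau = fit.tau
        rows.append(
            dict(
                conc_uM=float(conc),
                holding_mV=float(hp),
                tau_s=tau,
                final_inhibition=final,
                fitted=fitted,
            )
        )
        inhib.insert(0, "holding_mV", float(hp))
        inhib.insert(0, "conc_uM", float(conc))
        curve_frames.append(inhib)
    summary = pd.DataFrame(rows).sort_values(["holding_mV", "conc_uM"]).reset_index(drop=True)
    return KineticsAnalysis(
        summary=summary, fits=fits, curves=pd.concat(curve_frames, ignore_index=True)
    )


# ---------------------------------------------------------------------------
# open-state inactivation kinetics


def analyze_open_state_tau(
    traces_by_conc: Mapping[float, Sequence[pd.DataFrame]],
    *,
    settle_ms: float = 0.5,
) -> pd.DataFrame:
    """Open-state inactivation time constants from current decays.

    Each trace (``time_ms``, ``current_pA`` at the IV-peak step voltage) is
    fitted with a single exponential over its decay phase.  The fit starts
    ``settle_ms`` after the inward peak so the residual of the (much
    faster) activation mode does not bias the inactivation time constant.
    Returns mean +/- SD of tau per concentration.
    """
    rows = []
    for conc, traces in sorted(traces_by_conc.items()):
        taus = []
        for tr in traces:
            t = tr["time_ms"].to_numpy(dtype=float)
            i = tr["current_pA"].to_numpy(dtype=float)
            ipk = int(np.argmin(i))
            if ipk >= len(i) - 4:
                raise FitError("trace has no decay phase after the peak")
            start = ipk + int(np.searchsorted(t[ipk:] - t[ipk], settle_ms))
            start = min(start, len(i) - 5)
            seg_t = t[start:] - t[start]
            seg_y = i[start:] / i[ipk]  # normalized, decaying
            fit = fit_monoexp(seg_t, seg_y)  # t in ms -> K in 1/ms
            taus.append(fit.tau)
        taus = np.asarray(taus)
        rows.append(
            dict(
                conc_uM=float(conc),
                tau_ms_mean=taus.mean(),
                tau_ms_sd=taus.std(ddof=1) if len(taus) > 1 else 0.0,
                n=len(taus),
            )
        )
    return pd.DataFrame(rows)
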