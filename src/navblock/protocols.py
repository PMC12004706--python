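"""Declarative voltage-clamp protocols.

Six stimulus families used in automated patch-clamp pharmacology of Nav
channels are expressed as plain data objects (piecewise-constant voltage
segments with timing metadata).  The same objects drive both the gating
simulator and the downstream analyses, so protocol parameters live in one
place.

Protocol kinds
--------------
``activation``
    Current-voltage family: 500 ms test steps from -120 to +25 mV in 5 mV
    increments from a -120 mV holding potential.
``ssi``
    Steady-state inactivation: 500 ms conditioning prepulses over the same
    voltage grid, each followed by a 10 ms test pulse to -20 mV.
``slow_ssi``
    Slow-inactivation variant: long conditioning steps (1, 3, 5 or 10 s,
    one family per call), a 100 ms recovery interval at -120 mV to clear
    fast inactivation, then the 10 ms test pulse.
``state_dependence``
    Use-dependence assay: four holding-potential intervals (-110 to -80 mV
    in 10 mV increments), each delivering 180 x 20 ms depolarizations to
    0 mV at 1 Hz, with a recovery step to -120 mV between intervals.
``recovery``
    Recovery from inactivation: a conditioning prepulse to -20 mV (20, 500
    or 5000 ms), a recovery interval at -120 mV drawn from a log-spaced
    ladder, then a 10 ms test pulse to -20 mV.
``kinetics``
    Drug-equilibration time course: sparse 20 ms pulses to -20 mV from a
    fixed holding potential, spanning 3 minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Iterator

import pandas as pd

__all__ = [
    "VoltageSegment",
    "Sweep",
    "Protocol",
    "PROTOCOL_KINDS",
    "protocol_defaults",
    "build_protocol",
    "enumerate_sweeps",
    "protocol_to_json",
    "protocol_from_json",
    "protocol_table",
]

SEGMENT_LABELS = ("holding", "prepulse", "recovery", "test", "interpulse")

PROTOCOL_KINDS = (
    "activation",
    "ssi",
    "slow_ssi",
    "state_dependence",
    "recovery",
    "kinetics",
)

#: Sampling interval in ms (25 kHz digitization).
DEFAULT_SAMPLE_INTERVAL_MS = 0.04

META_KEYS = (
    "holding_potential",
    "step_voltage",
    "prepulse_duration",
    "recovery_interval",
    "pulse_number",
    "interval_index",
)


class ProtocolError(ValueError):
    """Raised for unknown protocol kinds or invalid overrides."""


@dataclass(frozen=True)
class VoltageSegment:
    """A constant command potential held for a fixed time.

    Parameters
    ----------
    level : float
        Command potential in mV; must lie within [-150, +80].
    duration : float
        Segment duration in ms; strictly positive.
    label : str
        One of ``holding``, ``prepulse``, ``recovery``, ``test``,
        ``interpulse``.
    """

    level: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")
        if not -150.0 <= self.level <= 80.0:
            raise ProtocolError(f"segment level {self.level} mV outside [-150, 80]")
        if self.label not in SEGMENT_LABELS:
            raise ProtocolError(f"unknown segment label {self.label!r}")


@dataclass(frozen=True)
class Sweep:
    """An ordered, contiguous run of voltage segments.

    ``start_time`` is the absolute onset of the first segment, in seconds
    from protocol start.  ``meta`` carries the protocol coordinates of the
    sweep (holding potential, step voltage, pulse number, ...) used by the
    analysis stages; keys absent from a protocol are ``None``.
    """

    segments: tuple[VoltageSegment, ...]
    start_time: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def test_onset_s(self) -> float:
        """Absolute onset (s) of the first segment labelled ``test``."""
        t = self.start_time
        for seg in self.segments:
            if seg.label == "test":
                return t
            t += seg.duration * 1e-3
        raise ProtocolError("sweep has no test segment")


@dataclass(frozen=True)
class Protocol:
    kind: str
    sweeps: tuple[Sweep, ...]
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL_MS
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        if not self.sweeps:
            raise ProtocolError("protocol must contain at least one sweep")
        n_test = [sum(1 for s in sw.segments if s.label == "test") for sw in self.sweeps]
        if any(n != 1 for n in n_test):
            raise ProtocolError(f"{self.kind}: every sweep must contain exactly one test segment")

    @property
    def duration_s(self) -> float:
        last = self.sweeps[-1]
        return last.start_time + last.duration_ms * 1e-3


# ---------------------------------------------------------------------------
# defaults

_DEFAULTS: dict[str, dict[str, Any]] = {
    "activation": dict(
        holding_potential=-120,
        v_start=-120,
        v_stop=25,
        v_step=5,
        test_duration_ms=500.0,
        inter_sweep_s=5.0,
    ),
    "ssi": dict(
        holding_potential=-120,
        prepulse_start=-120,
        prepulse_stop=25,
        prepulse_increment=5,
        prepulse_duration_ms=500.0,
        test_voltage=-20,
        test_duration_ms=10.0,
        inter_sweep_s=5.0,
    ),
    "slow_ssi": dict(
        holding_potential=-120,
        prepulse_start=-120,
        prepulse_stop=20,
        prepulse_increment=5,
        prepulse_duration_ms=1000.0,
        recovery_ms=100.0,
        test_voltage=-20,
        test_duration_ms=10.0,
        inter_sweep_s=5.0,
    ),
    "state_dependence": dict(
        holding_potentials=(-110, -100, -90, -80),
        n_pulses=180,
        pulse_voltage=0,
        pulse_duration_ms=20.0,
        period_s=1.0,
        recovery_potential=-120,
        inter_interval_recovery_s=30.0,
        pre_equilibration_s=0.0,
    ),
    "recovery": dict(
        holding_potential=-120,
        prepulse_voltage=-20,
        prepulse_duration_ms=20.0,
        recovery_intervals_ms=(1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 3000, 10000),
        test_voltage=-20,
        test_duration_ms=10.0,
        inter_sweep_s=5.0,
    ),
    "kinetics": dict(
        holding_potential=-90,
        test_voltage=-20,
        pulse_duration_ms=20.0,
        period_s=5.0,
        duration_s=180.0,
    ),
}


def protocol_defaults(kind: str) -> dict[str, Any]:
    """Return a copy of the default parameter map for ``kind``."""
    if kind not in _DEFAULTS:
        raise ProtocolError(f"unknown protocol kind {kind!r}")
    return dict(_DEFAULTS[kind])


def _resolve(kind: str, overrides: dict[str, Any]) -> dict[str, Any]:
    params = protocol_defaults(kind)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ProtocolError(f"{kind}: unknown override(s) {sorted(unknown)}")
    params.update(overrides)
    return params


def _voltage_grid(start: int, stop: int, step: int) -> list[int]:
    if step <= 0:
        raise ProtocolError(f"voltage increment must be positive, got {step}")
    start, stop, step = int(start), int(stop), int(step)
    grid = list(range(start, stop + 1, step))
    if not grid:
        raise ProtocolError("empty voltage grid")
    return grid


def _meta(**kw: Any) -> dict[str, Any]:
    m: dict[str, Any] = {k: None for k in META_KEYS}
    m.update(kw)
    return m


# ---------------------------------------------------------------------------
# builders (one per kind).  Each sweep carries its inter-sweep holding time
# as a leading segment so the protocol timeline is contiguous.


def _build_activation(p: dict[str, Any]) -> list[Sweep]:
    grid = _voltage_grid(p["v_start"], p["v_stop"], p["v_step"])
    sweeps, t = [], 0.0
    for v in grid:
        segs = (
            VoltageSegment(p["holding_potential"], p["inter_sweep_s"] * 1e3, "holding"),
            VoltageSegment(v, p["test_duration_ms"], "test"),
        )
        sw = Sweep(segs, t, _meta(holding_potential=p["holding_potential"], step_voltage=v))
        sweeps.append(sw)
        t += sw.duration_ms * 1e-3
    return sweeps


def _build_ssi(p: dict[str, Any]) -> list[Sweep]:
    grid = _voltage_grid(p["prepulse_start"], p["prepulse_stop"], p["prepulse_increment"])
    sweeps, t = [], 0.0
    for v in grid:
        segs = (
            VoltageSegment(p["holding_potential"], p["inter_sweep_s"] * 1e3, "holding"),
            VoltageSegment(v, p["prepulse_duration_ms"], "prepulse"),
            VoltageSegment(p["test_voltage"], p["test_duration_ms"], "test"),
        )
        sw = Sweep(
            segs,
            t,
            _meta(
                holding_potential=p["holding_potential"],
                step_voltage=v,
                prepulse_duration=p["prepulse_duration_ms"],
            ),
        )
        sweeps.append(sw)
        t += sw.duration_ms * 1e-3
    return sweeps


def _build_slow_ssi(p: dict[str, Any]) -> list[Sweep]:
    grid = _voltage_grid(p["prepulse_start"], p["prepulse_stop"], p["prepulse_increment"])
    sweeps, t = [], 0.0
    for v in grid:
        segs = (
            VoltageSegment(p["holding_potential"], p["inter_sweep_s"] * 1e3, "holding"),
            VoltageSegment(v, p["prepulse_duration_ms"], "prepulse"),
            VoltageSegment(p["holding_potential"], p["recovery_ms"], "recovery"),
            VoltageSegment(p["test_voltage"], p["test_duration_ms"], "test"),
        )
        sw = Sweep(
            segs,
            t,
            _meta(
                holding_potential=p["holding_potential"],
                step_voltage=v,
                prepulse_duration=p["prepulse_duration_ms"],
            ),
        )
        sweeps.append(sw)
        t += sw.duration_ms * 1e-3
    return sweeps


def _build_state_dependence(p: dict[str, Any]) -> list[Sweep]:
    if int(p["n_pulses"]) < 1:
        raise ProtocolError("state_dependence: n_pulses must be >= 1")
    sweeps, t = [], 0.0
    period_ms = p["period_s"] * 1e3
    interpulse_ms = period_ms - p["pulse_duration_ms"]
    if interpulse_ms <= 0:
        raise ProtocolError("state_dependence: pulse duration exceeds period")
    for i, hp in enumerate(p["holding_potentials"]):
        for n in range(1, int(p["n_pulses"]) + 1):
            lead: tuple[VoltageSegment, ...] = ()
            if n == 1 and i == 0 and p["pre_equilibration_s"] > 0:
                lead = (VoltageSegment(hp, p["pre_equilibration_s"] * 1e3, "holding"),)
            elif n == 1 and i > 0:
                lead = (
                    VoltageSegment(
                        p["recovery_potential"], p["inter_interval_recovery_s"] * 1e3, "recovery"
                    ),
                )
            segs = lead + (
                VoltageSegment(p["pulse_voltage"], p["pulse_duration_ms"], "test"),
                VoltageSegment(hp, interpulse_ms, "interpulse"),
            )
            sw = Sweep(
                segs,
                t,
                _meta(
                    holding_potential=hp,
                    step_voltage=p["pulse_voltage"],
                    pulse_number=n,
                    interval_index=i,
                ),
            )
            sweeps.append(sw)
            t += sw.duration_ms * 1e-3
    return sweeps


def _build_recovery(p: dict[str, Any]) -> list[Sweep]:
    intervals = tuple(p["recovery_intervals_ms"])
    if list(intervals) != sorted(intervals) or len(intervals) < 2:
        raise ProtocolError("recovery: intervals must be an increasing ladder")
    sweeps, t = [], 0.0
    for dt in intervals:
        segs = (
            VoltageSegment(p["holding_potential"], p["inter_sweep_s"] * 1e3, "holding"),
            VoltageSegment(p["prepulse_voltage"], p["prepulse_duration_ms"], "prepulse"),
            VoltageSegment(p["holding_potential"], float(dt), "recovery"),
            VoltageSegment(p["test_voltage"], p["test_duration_ms"], "test"),
        )
        sw = Sweep(
            segs,
            t,
            _meta(
                holding_potential=p["holding_potential"],
                step_voltage=p["test_voltage"],
                prepulse_duration=p["prepulse_duration_ms"],
                recovery_interval=float(dt),
            ),
        )
        sweeps.append(sw)
        t += sw.duration_ms * 1e-3
    return sweeps


def _build_kinetics(p: dict[str, Any]) -> list[Sweep]:
    period_ms = p["period_s"] * 1e3
    hold_ms = period_ms - p["pulse_duration_ms"]
    if hold_ms <= 0:
        raise ProtocolError("kinetics: pulse duration exceeds period")
    n_pulses = int(p["duration_s"] // p["period_s"]) + 1
    sweeps, t = [], 0.0
    for n in range(1, n_pulses + 1):
        segs = (
            VoltageSegment(p["holding_potential"], hold_ms, "holding"),
            VoltageSegment(p["test_voltage"], p["pulse_duration_ms"], "test"),
        )
        sw = Sweep(
            segs,
            t,
            _meta(
                holding_potential=p["holding_potential"],
                step_voltage=p["test_voltage"],
                pulse_number=n,
            ),
        )
        sweeps.append(sw)
        t += sw.duration_ms * 1e-3
    return sweeps


_BUILDERS = {
    "activation": _build_activation,
    "ssi": _build_ssi,
    "slow_ssi": _build_slow_ssi,
    "state_dependence": _build_state_dependence,
    "recovery": _build_recovery,
    "kinetics": _build_kinetics,
}


def build_protocol(kind: str, **overrides: Any) -> Protocol:
    """Construct a fully resolved :class:`Protocol`.

    Defaults reproduce the published protocol parameters (voltage grids,
    step durations, pulse counts); ``overrides`` replace individual named
    parameters without changing the protocol topology.

    Raises
    ------
    ProtocolError
        For an unknown kind, an unknown override name, or an override that
        produces an empty sweep list / non-positive duration.
    """
    params = _resolve(kind, overrides)
    sweeps = tuple(_BUILDERS[kind](params))
    return Protocol(kind=kind, sweeps=sweeps, params=params)


def enumerate_sweeps(protocol: Protocol) -> list[tuple[float, Sweep]]:
    """Return ``(absolute_start_s, sweep)`` pairs in stimulus order.

    Pure function of the protocol: start times are recomputed from segment
    durations and verified against the stored sweep timing.
    """
    out, t = [], 0.0
    for sw in protocol.sweeps:
        if abs(sw.start_time - t) > 1e-9:
            raise ProtocolError(
                f"sweep timing inconsistent: stored {sw.start_time} s, computed {t} s"
            )
        out.append((t, sw))
        t += sw.duration_ms * 1e-3
    return out


def iter_segments(protocol: Protocol) -> Iterator[tuple[float, Sweep, VoltageSegment]]:
    """Yield ``(absolute_start_s, sweep, segment)`` over the whole timeline."""
    for t0, sw in enumerate_sweeps(protocol):
        t = t0
        for seg in sw.segments:
            yield t, sw, seg
            t += seg.duration * 1e-3


# ---------------------------------------------------------------------------
# serialization


def protocol_to_json(protocol: Protocol) -> str:
    payload = {
        "kind": protocol.kind,
        "sample_interval": protocol.sample_interval,
        "params": protocol.params,
        "sweeps": [
            {
                "start_time": sw.start_time,
                "meta": sw.meta,
                "segments": [asdict(seg) for seg in sw.segments],
            }
            for sw in protocol.sweeps
        ],
    }
    return json.dumps(payload, indent=1)


def protocol_from_json(text: str) -> Protocol:
    payload = json.loads(text)
    sweeps = tuple(
        Sweep(
            segments=tuple(VoltageSegment(**seg) for seg in sw["segments"]),
            start_time=sw["start_time"],
            meta=sw["meta"],
        )
        for sw in payload["sweeps"]
    )
    params = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in payload.get("params", {}).items()
    }
    return Protocol(
        kind=payload["kind"],
        sweeps=sweeps,
        sample_interval=payload["sample_interval"],
        params=params,
    )


def protocol_table(protocol: Protocol) -> pd.DataFrame:
    """Resolved sweep table: one row per segment (for inspection / CLI)."""
    rows = []
    for i, (t0, sw) in enumerate(enumerate_sweeps(protocol)):
        t = t0
        for seg in sw.segments:
            rows.append(
                dict(
                    sweep_index=i,
                    start_s=round(t, 9),
                    segment_label=seg.label,
                    level_mV=seg.level,
                    duration_ms=seg.duration,
                )
            )
            t += seg.duration * 1e-3
    return pd.DataFrame(rows)
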