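"""Protocol runner and synthetic peak-current dataset generator.

The runner advances the seven-state occupancy vector segment by segment
(exact matrix-exponential propagation per constant-voltage segment, with
per-voltage propagators cached), evaluates the open probability on the
digitizer time grid inside measured segments, and records one peak-current
row per test pulse.  The dataset generator wraps the runner with the
features of an automated patch-clamp run: per-cell conductance and
quality-attribute variability, a single drug concentration per cell,
multiplicative peak noise, and a slow compound-independent rundown shared
by vehicle and drug cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .model import (
    CellParams,
    DrugParams,
    GatingParams,
    Propagator,
    STATES,
    equilibrium_state,
    free_equilibrium_state,
    rate_matrix,
)
from .protocols import Protocol, build_protocol, enumerate_sweeps

__all__ = [
    "PEAK_COLUMNS",
    "DatasetDesign",
    "run_protocol",
    "generate_dataset",
]

_O = STATES.index("O")

#: Column schema of the peak-record table (CSV-stable).
PEAK_COLUMNS = [
    "cell_id",
    "protocol",
    "holding_mV",
    "step_mV",
    "prepulse_ms",
    "recovery_ms",
    "pulse_number",
    "interval_index",
    "elapsed_s",
    "conc_uM",
    "peak_pA",
    "rm_MOhm",
    "rs_MOhm",
    "cap_pF",
]

#: Capacitive-transient surrogate: initial span of a measured segment
#: excluded from peak detection, ms.
DEFAULT_BLANK_MS = 0.5

# Protocols whose cells see the drug only from recording start (solution
# applied at t = 0): start from the drug-free gating equilibrium.  The
# remaining assays follow a 20 min pre-incubation, so they start from the
# full (drug-bound) equilibrium.
_FREE_INIT_KINDS = {"state_dependence", "kinetics"}


def _initial_state(
    kind: str, gating: GatingParams, drug: DrugParams, v0: float, conc: float, init: str
) -> np.ndarray:
    if init == "auto":
        init = "free" if kind in _FREE_INIT_KINDS else "full"
    if init == "free":
        return free_equilibrium_state(gating, drug, v0)
    if init == "full":
        return equilibrium_state(gating, drug, v0, conc)
    raise ValueError(f"unknown init mode {init!r}")


def run_protocol(
    cell: CellParams,
    gating: GatingParams,
    drug: DrugParams,
    protocol: Protocol,
    conc: float,
    *,
    init: str = "auto",
    pre_equilibration_s: float | None = None,
    record_traces: bool = False,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame] | None]:
    """Simulate one cell through one protocol.

    Parameters
    ----------
    conc : float
        Drug concentration in uM (0 = vehicle).
    init : {"auto", "free", "full"}
        Initial occupancy: gating equilibrium without bound drug
        (``free``; drug applied at recording start) or the full
        equilibrium including bound states (``full``; pre-incubated).
        ``auto`` picks ``free`` for the state-dependence and kinetics
        assays and ``full`` otherwise.
    pre_equilibration_s : float, optional
        Extra incubation at the first holding level before the protocol
        begins (e.g. an explicit 20 min drug equilibration from the
        drug-free state).
    record_traces : bool
        Keep the test-segment current traces (needed for open-state
        inactivation kinetics); keyed by sweep index.

    Returns
    -------
    records : pandas.DataFrame
        One row per test segment (plus one reference row with
        ``pulse_number = 0`` for the conditioning prepulse of recovery
        sweeps), schema :data:`PEAK_COLUMNS`.  Peaks are noise-free; noise
        and rundown are applied by :func:`generate_dataset`.
    traces : dict or None
        ``{sweep_index: DataFrame(time_ms, current_pA)}`` when requested.
    """
    sweeps = enumerate_sweeps(protocol)
    if not any(seg.label == "test" for _, sw in sweeps for seg in sw.segments):
        raise ValueError("protocol has no test segments")

    props: dict[float, Propagator] = {}

    def prop(v: float) -> Propagator:
        p = props.get(v)
        if p is None:
            p = Propagator(rate_matrix(gating, drug, v, conc))
            props[v] = p
        return p

    # initialize at the protocol's resting context: the first sweep's
    # holding potential (the first segment may already be a test pulse)
    first_sweep = sweeps[0][1]
    v0 = first_sweep.meta.get("holding_potential")
    if v0 is None:
        v0 = first_sweep.segments[0].level
    state = _initial_state(protocol.kind, gating, drug, v0, conc, init)
    if pre_equilibration_s:
        state = prop(v0).advance(state, pre_equilibration_s * 1e3)

    measure_prepulse = protocol.kind == "recovery"
    rows: list[dict[str, Any]] = []
    traces: dict[int, pd.DataFrame] = {}

    for sweep_index, (t0, sw) in enumerate(sweeps):
        t = t0
        for seg in sw.segments:
            measured = seg.label == "test" or (measure_prepulse and seg.label == "prepulse")
            p = prop(seg.level)
            if measured:
                grid = np.arange(0.0, seg.duration, protocol.sample_interval)
                occ = p.occupancy_series(state, grid)
                current = cell.g_max * occ[:, _O] * (seg.level - cell.e_na)
                sel = grid >= blank_ms
                window = current[sel] if sel.any() else current
                peak = float(window.min())  # inward = negative extremum
                meta = sw.meta
                rows.append(
                    dict(
                        cell_id="",
                        protocol=protocol.kind,
                        holding_mV=meta.get("holding_potential"),
                        step_mV=seg.level if seg.label == "prepulse" else meta.get("step_voltage"),
                        prepulse_ms=meta.get("prepulse_duration"),
                        recovery_ms=meta.get("recovery_interval"),
                        pulse_number=0 if seg.label == "prepulse" else meta.get("pulse_number"),
                        interval_index=meta.get("interval_index"),
                        elapsed_s=t,
                        conc_uM=conc,
                        peak_pA=peak,
                        rm_MOhm=np.nan,
                        rs_MOhm=np.nan,
                        cap_pF=cell.capacitance,
                    )
                )
                if record_traces and seg.label == "test":
                    traces[sweep_index] = pd.DataFrame(
                        {"time_ms": grid, "current_pA": current}
                    )
                state = p.advance(state, seg.duration)
            else:
                state = p.advance(state, seg.duration)
            t += seg.duration * 1e-3
            total = state.sum()
            # roundoff guard: scaling-and-squaring loses ~1e-10 per segment
            # (up to ~1e-8 for minutes-long equilibrations); renormalize and
            # treat anything worse as a numerical failure.
            if abs(total - 1.0) > 1e-6:  # pragma: no cover
                raise RuntimeError(f"occupancy drifted to {total}")
            state = state / total

    records = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    numeric = [c for c in PEAK_COLUMNS if c not in ("cell_id", "protocol")]
    records[numeric] = records[numeric].astype(float)
    return records, (traces if record_traces else None)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass(frozen=True)
class DatasetDesign:
    """Study design for a synthetic automated patch-clamp run.

    ``protocols`` maps protocol kind to an override dict (empty dict for
    defaults).  Every cell receives exactly one concentration and is run
    through every listed protocol; ``include_vehicle`` adds a 0 uM arm.
    """

    protocols: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {"state_dependence": {}}
    )
    concentrations: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    cells_per_concentration: int = 8
    include_vehicle: bool = True

    def __post_init__(self) -> None:
        if not self.protocols:
            raise ValueError("design must name at least one protocol")
        if not self.concentrations and not self.include_vehicle:
            raise ValueError("design must include at least one concentration")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.cells_per_concentration < 1:
            raise ValueError("cells_per_concentration must be >= 1")

    @property
    def all_concentrations(self) -> tuple[float, ...]:
        concs = tuple(self.concentrations)
        if self.include_vehicle and 0.0 not in concs:
            concs = (0.0,) + concs
        return concs


def _draw_cell_attrs(rng: np.random.Generator, template: CellParams) -> dict[str, float]:
    """Per-cell recording attributes, lognormal around plausible medians."""
    return dict(
        g_max=float(template.g_max * rng.lognormal(0.0, 0.3)),
        cap_pF=float(np.clip(rng.normal(template.capacitance, 2.0), 5.0, None)),
        rm_MOhm=float(rng.lognormal(np.log(1200.0), 0.4)),
        rs_MOhm=float(rng.lognormal(np.log(4.0), 0.3)),
    )


def generate_dataset(
    design: DatasetDesign,
    gating: GatingParams | None = None,
    drug: DrugParams | None = None,
    cell_template: CellParams | None = None,
    seed: int = 0,
    *,
    run_kwargs: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Generate a reproducible multi-cell peak-record table.

    Deterministic for a fixed seed: every cell draws from an independent
    substream keyed by (concentration index, cell index), so enlarging the
    design does not perturb existing cells.  Peak noise is multiplicative
    Gaussian; rundown is a shared exponential decay in elapsed recording
    time applied to vehicle and drug cells alike.

    Because occupancy dynamics are independent of ``g_max``, each
    (protocol, concentration) pair is simulated once and rescaled per cell.
    """
    gating = gating or GatingParams()
    drug = drug or DrugParams()
    cell_template = cell_template or CellParams()
    run_kwargs = run_kwargs or {}

    base_cache: dict[tuple[str, float], pd.DataFrame] = {}

    def base_records(kind: str, overrides: dict[str, Any], conc: float) -> pd.DataFrame:
        key = (kind + repr(sorted(overrides.items())), conc)
        if key not in base_cache:
            protocol = build_protocol(kind, **overrides)
            rec, _ = run_protocol(
                cell_template, gating, drug, protocol, conc, **run_kwargs
            )
            base_cache[key] = rec
        return base_cache[key]

    frames = []
    for ci, conc in enumerate(design.all_concentrations):
        for cell_i in range(design.cells_per_concentration):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, cell_i))
            rng = np.random.default_rng(ss)
            attrs = _draw_cell_attrs(rng, cell_template)
            cell_id = f"c{conc:g}uM_{cell_i:02d}"
            for kind, overrides in design.protocols.items():
                rec = base_records(kind, overrides, conc).copy()
                scale = attrs["g_max"] / cell_template.g_max
                noise = rng.normal(1.0, cell_template.peak_noise_sigma, size=len(rec))
                rundown = np.exp(
                    -cell_template.rundown_rate * rec["elapsed_s"].to_numpy() / 60.0
                )
                rec["peak_pA"] = rec["peak_pA"].to_numpy() * scale * noise * rundown
                rec["cell_id"] = cell_id
                rec["rm_MOhm"] = attrs["rm_MOhm"]
                rec["rs_MOhm"] = attrs["rs_MOhm"]
                rec["cap_pF"] = attrs["cap_pF"]
                frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    return out[PEAK_COLUMNS]


def write_peak_table(records: pd.DataFrame, path: str) -> None:
    """Write a peak-record table as CSV with the canonical column order."""
    records[PEAK_COLUMNS].to_csv(path, index=False)


def read_peak_table(path: str) -> pd.DataFrame:
    """Read a peak-record CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df[PEAK_COLUMNS]
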