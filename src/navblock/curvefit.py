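"""Fitting primitives for patch-clamp pharmacology.

Hill-Langmuir concentration-response, Boltzmann voltage dependence,
mono-exponential and bi-exponential time courses, plus the current-to-
conductance transform and reversal-potential estimation.  All fitters are
bounded nonlinear least squares with a fixed multistart grid, so results
are deterministic given identical inputs; standard errors come from the
parameter covariance at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitError",
    "HillFit",
    "NoInhibition",
    "BoltzmannFit",
    "ExpFit",
    "BiexpFit",
    "IVRecord",
    "hill",
    "fit_hill",
    "boltzmann",
    "fit_boltzmann",
    "fit_monoexp",
    "fit_biexp",
    "estimate_reversal",
    "nernst_potential",
    "conductance_from_iv",
]


class FitError(RuntimeError):
    """Raised when a fit is infeasible or the input is degenerate."""


# ---------------------------------------------------------------------------
# generic bounded multistart least squares


def _multistart_ls(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-multistart trust-region least squares.

    Ties on the residual norm (within 1e-12 relative) break toward the
    lexicographically smallest parameter vector, making the result a pure
    function of the inputs and the start grid.
    """
    lo, hi = bounds
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        cand = (sol.cost, sol.x, sol.jac)
        if best is None:
            best = cand
        else:
            rel = (best[0] - sol.cost) / max(best[0], 1e-300)
            if rel > 1e-12 or (abs(rel) <= 1e-12 and tuple(sol.x) < tuple(best[1])):
                best = cand
    if best is None:
        raise FitError("least-squares optimization failed from every start")
    cost, x, jac = best
    n, p = jac.shape
    resid_var = 2.0 * cost / max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * resid_var
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(p, np.nan)
    return x, stderr, math.sqrt(2.0 * cost)


def _serialize(obj) -> str:
    return json.dumps(asdict(obj), default=float, indent=1)


# ---------------------------------------------------------------------------
# Hill-Langmuir


def hill(conc: np.ndarray, ic50: float, h: float) -> np.ndarray:
    """Normalized inhibition ``C^h / (IC50^h + C^h)``."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    ratio = (conc[pos] / ic50) ** h
    out[pos] = ratio / (1.0 + ratio)
    return out


@dataclass(frozen=True)
class NoInhibition:
    """Sentinel returned when responses are indistinguishable from zero."""

    max_response: float
    threshold: float

    def to_json(self) -> str:
        return _serialize(self)


@dataclass(frozen=True)
class HillFit:
    ic50: float  # uM
    hill: float
    slope_fixed: bool
    ic50_stderr: float
    hill_stderr: float
    residual_norm: float

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return hill(conc, self.ic50, self.hill)

    def to_json(self) -> str:
        return _serialize(self)


def fit_hill(
    conc: Sequence[float],
    response: Sequence[float],
    fix_slope: float | None = None,
    *,
    no_inhibition_threshold: float = 0.1,
) -> HillFit | NoInhibition:
    """Fit the Hill-Langmuir equation to normalized inhibition data.

    Requires at least three distinct positive concentrations for a free
    slope (two when the slope is fixed) and responses within [-0.2, 1.2].
    Returns :class:`NoInhibition` instead of a fit when every response is
    below ``no_inhibition_threshold``.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("conc and response must have the same length")
    if np.any((y < -0.2) | (y > 1.2)):
        raise ValueError("responses outside [-0.2, 1.2]; check normalization")
    if float(np.max(y)) < no_inhibition_threshold:
        return NoInhibition(float(np.max(y)), no_inhibition_threshold)
    n_distinct = len(set(conc[conc > 0]))
    needed = 2 if fix_slope is not None else 3
    if n_distinct < needed:
        raise FitError(f"need >= {needed} distinct positive concentrations, got {n_distinct}")

    cpos = conc[conc > 0]
    log_lo, log_hi = math.log10(cpos.min()), math.log10(cpos.max())
    ic50_starts = np.logspace(log_lo - 1, log_hi + 1, 7)

    if fix_slope is not None:
        def residual(x: np.ndarray) -> np.ndarray:
            return hill(conc, x[0], fix_slope) - y

        starts = [np.array([s]) for s in ic50_starts]
        bounds = (np.array([1e-3]), np.array([1e5]))
        x, se, rn = _multistart_ls(residual, starts, bounds)
        return HillFit(float(x[0]), float(fix_slope), True, float(se[0]), 0.0, rn)

    def residual(x: np.ndarray) -> np.ndarray:
        return hill(conc, x[0], x[1]) - y

    starts = [np.array([s, h0]) for s in ic50_starts for h0 in (0.7, 1.0, 1.5)]
    bounds = (np.array([1e-3, 0.3]), np.array([1e5, 3.0]))
    x, se, rn = _multistart_ls(residual, starts, bounds)
    return HillFit(float(x[0]), float(x[1]), False, float(se[0]), float(se[1]), rn)


# ---------------------------------------------------------------------------
# Boltzmann


def boltzmann(v: np.ndarray, v_half: float, k: float, amplitude: float, direction: str) -> np.ndarray:
    """Sigmoid voltage dependence with positive slope factor ``k``.

    ``activation``: rises with depolarization (conductance activation).
    ``inactivation``: falls with depolarization (availability).
    """
    v = np.asarray(v, dtype=float)
    sign = -1.0 if direction == "activation" else 1.0
    return amplitude / (1.0 + np.exp(sign * (v - v_half) / k))


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float  # mV
    k: float  # mV, always positive; see direction
    amplitude: float
    direction: str  # "activation" | "inactivation"
    v_half_stderr: float
    k_stderr: float
    residual_norm: float

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(v, self.v_half, self.k, self.amplitude, self.direction)

    def availability(self, v: float) -> float:
        """Unit-amplitude availability at ``v`` (inactivation convention)."""
        if self.direction != "inactivation":
            raise ValueError("availability is defined for inactivation fits")
        return 1.0 / (1.0 + math.exp((v - self.v_half) / self.k))

    def to_json(self) -> str:
        return _serialize(self)


def fit_boltzmann(
    v: Sequence[float], y: Sequence[float], direction: str = "inactivation"
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of normalized conductance/availability.

    Needs at least four voltages spanning both sides of the transition.
    Raises :class:`FitError` for non-sigmoidal input (no better than a
    constant model).
    """
    if direction not in ("activation", "inactivation"):
        raise ValueError("direction must be 'activation' or 'inactivation'")
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.shape != y.shape or len(v) < 4:
        raise FitError("need >= 4 (voltage, response) points")
    if np.ptp(y) < 0.05:
        raise FitError("no transition in the data: response span < 0.05")

    def residual(x: np.ndarray) -> np.ndarray:
        return boltzmann(v, x[0], x[1], x[2], direction) - y

    qs = np.quantile(v, [0.2, 0.4, 0.5, 0.6, 0.8])
    starts = [np.array([vh, k0, 1.0]) for vh in qs for k0 in (4.0, 8.0, 15.0)]
    bounds = (np.array([v.min() - 50.0, 0.5, 0.05]), np.array([v.max() + 50.0, 30.0, 10.0]))
    x, se, rn = _multistart_ls(residual, starts, bounds)
    sse_fit = rn**2
    sse_const = float(np.sum((y - y.mean()) ** 2))
    if sse_fit >= sse_const:
        raise FitError("non-sigmoidal input: Boltzmann fit no better than a constant")
    return BoltzmannFit(
        float(x[0]), float(x[1]), float(x[2]), direction, float(se[0]), float(se[1]), rn
    )


# ---------------------------------------------------------------------------
# exponentials


@dataclass(frozen=True)
class ExpFit:
    y0: float
    plateau: float
    k: float  # 1/s
    y0_stderr: float
    plateau_stderr: float
    k_stderr: float
    residual_norm: float

    @property
    def tau(self) -> float:
        """Time constant 1/K, seconds."""
        return 1.0 / self.k

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * t) + self.plateau

    def to_json(self) -> str:
        return _serialize(self)


def fit_monoexp(t: Sequence[float], y: Sequence[float]) -> ExpFit:
    """Fit ``Y = (Y0 - Plateau) * exp(-K t) + Plateau`` (t in seconds)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or len(t) < 4:
        raise FitError("need >= 4 (t, y) points")
    if np.any(np.diff(t) <= 0):
        raise FitError("t must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite values in y")
    span = float(np.ptp(y))
    if span < 1e-12 or span < 1e-6 * max(abs(y).max(), 1e-300):
        raise FitError("constant series: rate unidentifiable")

    t_span = t[-1] - t[0]
    k_starts = np.logspace(math.log10(0.1 / t_span), math.log10(50.0 / t_span), 7)

    def residual(x: np.ndarray) -> np.ndarray:
        return (x[0] - x[1]) * np.exp(-x[2] * t) + x[1] - y

    ylo, yhi = y.min() - 2 * span, y.max() + 2 * span
    starts = [np.array([y[0], y[-1], k0]) for k0 in k_starts]
    bounds = (np.array([ylo, ylo, 1e-6]), np.array([yhi, yhi, 1e6]))
    x, se, rn = _multistart_ls(residual, starts, bounds)
    return ExpFit(
        float(x[0]), float(x[1]), float(x[2]), float(se[0]), float(se[1]), float(se[2]), rn
    )


@dataclass(frozen=True)
class BiexpFit:
    y0: float
    plateau: float
    percent_fast: float  # 0..100
    k_fast: float  # 1/s
    k_slow: float  # 1/s
    degenerate: bool
    residual_norm: float

    @property
    def span_fast(self) -> float:
        return (self.y0 - self.plateau) * self.percent_fast * 0.01

    @property
    def span_slow(self) -> float:
        return (self.y0 - self.plateau) * (100.0 - self.percent_fast) * 0.01

    @property
    def tau_fast(self) -> float:
        return 1.0 / self.k_fast

    @property
    def tau_slow(self) -> float:
        return 1.0 / self.k_slow

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.plateau
            + self.span_fast * np.exp(-self.k_fast * t)
            + self.span_slow * np.exp(-self.k_slow * t)
        )

    def to_json(self) -> str:
        return _serialize(self)


def fit_biexp(t: Sequence[float], y: Sequence[float]) -> BiexpFit:
    """Fit the two-component exponential (spans tied to Y0 and plateau).

    ``k_fast >= k_slow`` is enforced by relabeling after the fit.  A fit
    that collapses onto a single exponential is returned with
    ``percent_fast`` at its boundary and ``degenerate=True``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or len(t) < 6:
        raise FitError("need >= 6 (t, y) points")
    tpos = t[t > 0]
    if len(tpos) == 0 or tpos.max() / tpos.min() < 10.0:
        raise FitError("t must span at least one decade")
    span = float(np.ptp(y))
    if span < 1e-12:
        raise FitError("constant series: rates unidentifiable")

    t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0

    def residual(x: np.ndarray) -> np.ndarray:
        y0, plateau, pf, k1, k2 = x
        sf = (y0 - plateau) * pf * 0.01
        ss = (y0 - plateau) * (100.0 - pf) * 0.01
        return plateau + sf * np.exp(-k1 * t) + ss * np.exp(-k2 * t) - y

    k_grid = np.logspace(math.log10(0.2 / t_span), math.log10(200.0 / t_span), 5)
    starts = [
        np.array([y[0], y[-1], pf0, kf, kf / ratio])
        for pf0 in (30.0, 70.0)
        for kf in k_grid
        for ratio in (10.0, 100.0)
    ]
    ylo, yhi = y.min() - 2 * span, y.max() + 2 * span
    bounds = (
        np.array([ylo, ylo, 0.0, 1e-6, 1e-6]),
        np.array([yhi, yhi, 100.0, 1e6, 1e6]),
    )
    x, _, rn = _multistart_ls(residual, starts, bounds)
    y0, plateau, pf, k1, k2 = (float(val) for val in x)
    if k1 < k2:  # relabel so fast >= slow
        k1, k2, pf = k2, k1, 100.0 - pf
    degenerate = k1 / k2 < 1.05 or pf <= 0.5 or pf >= 99.5
    return BiexpFit(y0, plateau, pf, k1, k2, degenerate, rn)


# ---------------------------------------------------------------------------
# IV relationship helpers


@dataclass(frozen=True)
class IVRecord:
    """One point of a current-voltage relationship."""

    v: float  # mV
    i: float  # pA
    g: float | None = None  # nS, filled by conductance_from_iv
    excluded: bool = False


def _iv_arrays(iv: Sequence[IVRecord] | Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(iv) == 0:
        raise ValueError("empty IV relationship")
    first = iv[0]
    if isinstance(first, IVRecord):
        v = np.array([r.v for r in iv], dtype=float)
        i = np.array([r.i for r in iv], dtype=float)
    else:
        arr = np.asarray(iv, dtype=float)
        v, i = arr[:, 0], arr[:, 1]
    order = np.argsort(v)
    return v[order], i[order]


def estimate_reversal(iv: Sequence[IVRecord] | Sequence[tuple[float, float]]) -> float:
    """Zero-crossing voltage of the IV relationship, by linear interpolation.

    Requires both inward and outward limbs (a sign change).  Raises
    :class:`FitError` advising the Nernst fallback otherwise.
    """
    v, i = _iv_arrays(iv)
    sign = np.sign(i)
    crossings = np.where(sign[:-1] * sign[1:] < 0)[0]
    zeros = np.where(sign == 0)[0]
    if len(zeros):
        return float(v[zeros[0]])
    if len(crossings) == 0:
        raise FitError(
            "IV has no sign change; estimate E_Na from solution compositions "
            "with nernst_potential()"
        )
    j = crossings[-1]  # crossing nearest the outward limb
    frac = -i[j] / (i[j + 1] - i[j])
    return float(v[j] + frac * (v[j + 1] - v[j]))


def nernst_potential(out_mM: float, in_mM: float, temperature_c: float = 22.0) -> float:
    """Nernst equilibrium potential (mV) for a monovalent cation."""
    if out_mM <= 0 or in_mM <= 0:
        raise ValueError("concentrations must be positive")
    R, F = 8.31446, 96485.33
    T = temperature_c + 273.15
    return 1e3 * R * T / F * math.log(out_mM / in_mM)


def conductance_from_iv(
    iv: Sequence[IVRecord] | Sequence[tuple[float, float]],
    e_na: float,
    exclusion_mV: float = 2.0,
) -> list[IVRecord]:
    """Chord conductance ``G = I / (V - E_Na)`` per IV point (nS).

    Points within ``exclusion_mV`` of the reversal potential are excluded
    and flagged (the transform is singular there).
    """
    if not math.isfinite(e_na):
        raise ValueError("e_na must be finite")
    v, i = _iv_arrays(iv)
    out = []
    for vj, ij in zip(v, i):
        if abs(vj - e_na) < exclusion_mV:
            out.append(IVRecord(float(vj), float(ij), None, True))
        else:
            out.append(IVRecord(float(vj), float(ij), float(ij / (vj - e_na)), False))
    return out
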