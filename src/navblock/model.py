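"""Seven-state Markov model of Nav gating with state-dependent drug binding.

The channel is described by four free states and three drug-bound states::

          C <---> O ---> IF <---> IS          (free gating)
          |               |        |
          CB <--------> IFB <---> ISB         (drug bound; no bound-open state)

``C`` closed/resting, ``O`` open, ``IF`` fast-inactivated, ``IS``
slow-inactivated; the ``*B`` states are the drug-bound counterparts.  The
drug associates with resting and inactivated conformations only (the
modulated-receptor picture for a neutral, highly lipophilic compound that
reaches the pore through the fenestrations): binding edges run C->CB,
IF->IFB and IS->ISB at rate ``k_on * conc``; unbinding rates are
``k_on * K_R`` from CB and ``k_on * K_I`` from IFB/ISB, so the resting and
inactivated dissociation constants are exactly ``K_R`` and ``K_I``.

All rates are constructed to satisfy detailed balance, so the stationary
distribution at any fixed voltage is the Gibbs measure over state weights
and closed-form equilibrium quantities (availability, apparent IC50,
fractional block) are exact.  Gating transitions among the bound states
mirror the free ones, rescaled by ``sqrt(K_R/K_I)`` so that every
binding/gating cycle has unit rate-ratio product (microscopic
reversibility); equivalently, the inactivation equilibrium of bound
channels is shifted by the factor K_R/K_I.

Units: time in ms, voltage in mV, concentration in uM.  ``DrugParams.k_on``
is given in the conventional 1/(uM*s) and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

__all__ = [
    "STATES",
    "GatingParams",
    "DrugParams",
    "CellParams",
    "default_gating",
    "conductance_assay_gating",
    "default_drug",
    "default_cell",
    "no_resting_block_drug",
    "steady_state_availability",
    "equilibrium_apparent_ic50",
    "equilibrium_block",
    "rate_matrix",
    "equilibrium_state",
    "free_equilibrium_state",
    "Propagator",
    "propagate",
]

STATES = ("C", "O", "IF", "IS", "CB", "IFB", "ISB")
_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class GatingParams:
    """Voltage-dependent gating parameters of the drug-free channel.

    Boltzmann midpoints/slopes set the equilibrium voltage dependences;
    the rate scales (per ms) set how fast those equilibria are approached.

    Attributes
    ----------
    act_v_half, act_slope : float
        Midpoint (mV) and slope (mV, > 0) of the closed<->open equilibrium.
    ssi_v_half, ssi_slope : float
        Midpoint and slope of steady-state availability: at full gating
        equilibrium the non-inactivated fraction is
        ``1 / (1 + exp((v - ssi_v_half)/ssi_slope))``.
    act_rate : float
        Base rate (1/ms) of the activation/deactivation pair.
    open_inact_rate : float
        O -> IF rate (1/ms); sets the open-state inactivation time constant
        at depolarized potentials.
    inact_rate : float
        Base rate (1/ms) of the closed<->fast-inactivated pair.
    slow_entry, slow_exit : float
        IF <-> IS rates (1/ms), voltage independent.
    """

    act_v_half: float = -37.0
    act_slope: float = 7.0
    ssi_v_half: float = -80.0
    ssi_slope: float = 8.0
    act_rate: float = 3.0
    open_inact_rate: float = 1.5
    inact_rate: float = 0.05
    slow_entry: float = 5e-5
    slow_exit: float = 1e-3

    def __post_init__(self) -> None:
        if self.act_slope <= 0 or self.ssi_slope <= 0:
            raise ValueError("Boltzmann slopes must be positive")
        for name in ("act_rate", "open_inact_rate", "inact_rate", "slow_entry", "slow_exit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def slow_ratio(self) -> float:
        """Equilibrium IS/IF occupancy ratio."""
        return self.slow_entry / self.slow_exit if self.slow_exit > 0 else 0.0


@dataclass(frozen=True)
class DrugParams:
    """Two-affinity (modulated receptor) drug parameters.

    ``k_r`` and ``k_i`` are the dissociation constants (uM) for resting and
    inactivated channels; ``k_on`` is the shared association rate in
    1/(uM*s).  The open state carries no binding edge.
    """

    k_r: float = 108.0
    k_i: float = 3.6
    k_on: float = 0.002

    def __post_init__(self) -> None:
        if self.k_r <= 0 or self.k_i <= 0 or self.k_on <= 0:
            raise ValueError("K_R, K_I and k_on must be positive")

    @property
    def k_on_per_ms(self) -> float:
        return self.k_on * 1e-3

    @property
    def k_off_r(self) -> float:
        """Unbinding rate from CB, 1/ms."""
        return self.k_on_per_ms * self.k_r

    @property
    def k_off_i(self) -> float:
        """Unbinding rate from IFB/ISB, 1/ms."""
        return self.k_on_per_ms * self.k_i

    @property
    def fold_preference(self) -> float:
        return self.k_r / self.k_i


@dataclass(frozen=True)
class CellParams:
    """Per-cell recording parameters for the synthetic-data generator."""

    g_max: float = 50.0  # nS
    capacitance: float = 15.0  # pF
    e_na: float = 68.0  # mV (Nernst for 145/10 mM Na at 22 C)
    peak_noise_sigma: float = 0.05  # multiplicative, per peak
    rundown_rate: float = 0.01  # fraction per minute
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.capacitance <= 0:
            raise ValueError("g_max and capacitance must be positive")
        if self.peak_noise_sigma < 0:
            raise ValueError("peak_noise_sigma must be >= 0")


def default_gating() -> GatingParams:
    return GatingParams()


def conductance_assay_gating() -> GatingParams:
    """Gating profile calibrated for the maximal-conductance (IV) assay.

    The long 500 ms depolarizations of the conductance protocol drive
    channels into deep slow-inactivated states that the brief 20 ms pulses
    of the use-dependence assay barely touch.  This profile strengthens the
    slow-inactivation coupling (faster entry, much slower exit) so that a
    30 uM exposure halves the maximal conductance through accumulation of
    drug-bound slow-inactivated channels, while the base defaults keep slow
    inactivation mild for the state-dependence analyses.
    """
    return replace(default_gating(), slow_entry=1e-3, slow_exit=1e-5)


def default_drug() -> DrugParams:
    return DrugParams()


def no_resting_block_drug() -> DrugParams:
    """Drug variant with negligible resting-state affinity (K_R -> large)."""
    return replace(default_drug(), k_r=1e4)


def default_cell(seed: int = 0) -> CellParams:
    return CellParams(seed=seed)


# ---------------------------------------------------------------------------
# closed-form equilibrium quantities


def steady_state_availability(gating: GatingParams, v: float) -> float:
    """Equilibrium non-inactivated fraction at holding potential ``v``.

    Boltzmann in ``(ssi_v_half, ssi_slope)``; monotonically decreasing with
    depolarization.  Valid where open-state occupancy is negligible
    (holding potentials well below the activation range).
    """
    return 1.0 / (1.0 + math.exp((v - gating.ssi_v_half) / gating.ssi_slope))


def equilibrium_apparent_ic50(drug: DrugParams, availability: float) -> float:
    """Apparent IC50 (uM) at a holding potential with the given availability.

    The availability-weighted harmonic mix of the two dissociation
    constants: ``1 / (h/K_R + (1-h)/K_I)``.  Lies between min(K_R, K_I)
    and max(K_R, K_I).
    """
    if not 0.0 <= availability <= 1.0:
        raise ValueError(f"availability must be in [0, 1], got {availability}")
    return 1.0 / (availability / drug.k_r + (1.0 - availability) / drug.k_i)


def equilibrium_block(gating: GatingParams, drug: DrugParams, v: float, conc: float) -> float:
    """Closed-form equilibrium fractional block of the peak current at ``v``."""
    ic50 = equilibrium_apparent_ic50(drug, steady_state_availability(gating, v))
    return conc / (conc + ic50)


# ---------------------------------------------------------------------------
# generator matrix


def _gating_rates(gating: GatingParams, v: float) -> dict[str, float]:
    """Voltage-dependent transition rates (1/ms) of the free channel."""
    g = gating
    # activation / deactivation: equilibrium O/C = exp((v - Va)/ka)
    ya = (v - g.act_v_half) / g.act_slope
    alpha = g.act_rate * math.exp(0.5 * ya)
    beta = g.act_rate * math.exp(-0.5 * ya)
    # closed <-> fast-inactivated; equilibrium (IF+IS)/C = exp((v - Vs)/ks)
    # i.e. IF/C = exp(.)/(1 + slow_ratio) so that total availability is the
    # stated Boltzmann once IS is included.
    r = g.slow_ratio
    s = math.sqrt(math.exp((v - g.ssi_v_half) / g.ssi_slope) / (1.0 + r))
    s = min(max(s, 1e-9), 1e9)  # overflow guard only; ratio left exact
    k_ci = g.inact_rate * s
    k_ic = g.inact_rate / s
    # O -> IF, with the reverse rate fixed by the C-O-IF cycle identity
    # (alpha/beta) * (k_oi/k_io) * (k_ic/k_ci) = 1  => detailed balance.
    k_oi = g.open_inact_rate
    k_io = k_oi * math.exp(ya) * k_ic / k_ci if k_ci > 0 else 0.0
    return dict(
        alpha=alpha,
        beta=beta,
        k_ci=k_ci,
        k_ic=k_ic,
        k_oi=k_oi,
        k_io=k_io,
        k_fs=g.slow_entry,
        k_sf=g.slow_exit,
    )


def rate_matrix(
    gating: GatingParams, drug: DrugParams, v: float, conc: float
) -> np.ndarray:
    """Generator matrix Q (7x7, 1/ms) at voltage ``v`` and drug ``conc`` (uM).

    Convention: ``d s / dt = Q @ s`` for a column occupancy vector ``s``
    ordered as :data:`STATES`; off-diagonal ``Q[i, j]`` is the j -> i rate
    and every column sums to zero.

    The bound-state gating pair CB <-> IFB mirrors the free C <-> IF pair
    scaled by ``sqrt(K_R/K_I)`` in the forward direction and
    ``sqrt(K_I/K_R)`` in the backward direction, which makes the product of
    rate ratios around the cycle C-CB-IFB-IF-C equal to one.  IF <-> IS
    rates are reused unchanged for IFB <-> ISB (both bound states unbind
    with K_I, so that cycle is balanced trivially).
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    r = _gating_rates(gating, v)
    scale = math.sqrt(drug.k_r / drug.k_i)
    kon = drug.k_on_per_ms * conc

    Q = np.zeros((7, 7))

    def add(src: str, dst: str, rate: float) -> None:
        i, j = _IDX[dst], _IDX[src]
        Q[i, j] += rate
        Q[j, j] -= rate

    # free gating
    add("C", "O", r["alpha"])
    add("O", "C", r["beta"])
    add("O", "IF", r["k_oi"])
    add("IF", "O", r["k_io"])
    add("C", "IF", r["k_ci"])
    add("IF", "C", r["k_ic"])
    add("IF", "IS", r["k_fs"])
    add("IS", "IF", r["k_sf"])
    # binding / unbinding (no open-state edge)
    add("C", "CB", kon)
    add("CB", "C", drug.k_off_r)
    add("IF", "IFB", kon)
    add("IFB", "IF", drug.k_off_i)
    add("IS", "ISB", kon)
    add("ISB", "IS", drug.k_off_i)
    # bound gating
    add("CB", "IFB", r["k_ci"] * scale)
    add("IFB", "CB", r["k_ic"] / scale)
    add("IFB", "ISB", r["k_fs"])
    add("ISB", "IFB", r["k_sf"])

    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite entries in rate matrix")
    return Q


# ---------------------------------------------------------------------------
# propagation


class Propagator:
    """Exact linear evolution under a constant generator matrix.

    State advancement uses matrix exponentials (scaling-and-squaring, which
    conserves total occupancy to machine precision even for stiff
    generators), cached per duration since protocols reuse a small set of
    segment lengths.  Dense occupancy series for trace evaluation use the
    eigendecomposition, computed once per matrix.
    """

    def __init__(self, Q: np.ndarray):
        if not np.all(np.isfinite(Q)):
            raise ValueError("non-finite entries in generator matrix")
        self.Q = np.asarray(Q, dtype=float)
        self._expm_cache: dict[float, np.ndarray] = {}
        self._eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def _propagator(self, duration_ms: float) -> np.ndarray:
        P = self._expm_cache.get(duration_ms)
        if P is None:
            P = scipy.linalg.expm(self.Q * duration_ms)
            self._expm_cache[duration_ms] = P
        return P

    def advance(self, state: np.ndarray, duration_ms: float) -> np.ndarray:
        """Return the occupancy vector after ``duration_ms`` at constant V."""
        if duration_ms < 0:
            raise ValueError("duration must be >= 0")
        if duration_ms == 0:
            return np.asarray(state, dtype=float).copy()
        out = self._propagator(duration_ms) @ state
        return np.clip(out, 0.0, None)

    def occupancy_series(self, state: np.ndarray, times_ms: np.ndarray) -> np.ndarray:
        """Occupancies at the given times (shape ``(n_times, n_states)``)."""
        times_ms = np.asarray(times_ms, dtype=float)
        if self._eig is None:
            w, V = np.linalg.eig(self.Q)
            self._eig = (w, V, np.linalg.inv(V))
        w, V, Vinv = self._eig
        coef = Vinv @ state
        phases = np.exp(np.outer(times_ms, w)) * coef
        out = (phases @ V.T).real
        return np.clip(out, 0.0, None)

    def equilibrium(self) -> np.ndarray:
        """Stationary distribution (null vector of Q, normalized)."""
        ns = scipy.linalg.null_space(self.Q, rcond=1e-10)
        if ns.shape[1] == 0:  # pragma: no cover
            # fall back to the eigenvector of the smallest-magnitude eigenvalue
            w, V = np.linalg.eig(self.Q)
            vec = V[:, np.argmin(np.abs(w))].real
        else:
            vec = ns[:, 0]
        vec = np.abs(vec)
        return vec / vec.sum()


def propagate(state: np.ndarray, Q: np.ndarray, duration_ms: float) -> np.ndarray:
    """One-shot exact propagation of ``state`` under ``Q`` for ``duration_ms``."""
    state = np.asarray(state, dtype=float)
    _check_state(state)
    out = Propagator(Q).advance(state, duration_ms)
    return out


def _check_state(state: np.ndarray) -> None:
    if state.shape != (7,):
        raise ValueError(f"state vector must have shape (7,), got {state.shape}")
    if np.any(state < -1e-12) or abs(state.sum() - 1.0) > 1e-8:
        raise ValueError("state occupancies must be non-negative and sum to 1")


def equilibrium_state(
    gating: GatingParams, drug: DrugParams, v: float, conc: float
) -> np.ndarray:
    """Full stationary occupancy (free + bound) at ``v`` and ``conc``."""
    return Propagator(rate_matrix(gating, drug, v, conc)).equilibrium()


def free_equilibrium_state(gating: GatingParams, drug: DrugParams, v: float) -> np.ndarray:
    """Gating equilibrium with zero bound occupancy (drug just applied)."""
    return equilibrium_state(gating, drug, v, 0.0)
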