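"""Ten-state Markov model of the large-conductance Ca2+-activated K+
(BK) channel.

The scheme has five closed states C0..C4 and five open states O0..O4.
Horizontal transitions along each row bind/unbind Ca2+ with rates
proportional to the intracellular concentration ``cai``:

    C0->C1: 3*K_on*cai   C1->C2: 4*K_on*cai   C2->C3: 3*K_on*cai   C3->C4: K_on*cai
    C1->C0: K_coff*cai   C2->C1: 3*K_coff*cai C3->C2: 4*K_coff*cai C4->C3: 3*K_coff*cai

with the same pattern on the open row using ``K_ooff`` for unbinding.
Vertical transitions Ci<->Oi are voltage dependent through the factors
``a = exp(V / a_efold)`` (opening) and ``b = exp(-V / b_efold)``
(closing); the O4->C4 rate additionally carries a ``cai`` factor.  The
unbinding rates scale with ``cai`` as well; that Ca-dependence of
unbinding is unusual for an aggregated gating scheme but is retained
exactly as specified.

Note the exponential voltage factors ``a`` and ``b`` with configurable
e-fold slopes (default 25 mV, hyperpolarization favouring closed) are a
modelling choice of this package; see docs/methods.md.

The channel current is ``I_BK = gmax * O * (V - E_K)`` where the
conducting open probability ``O`` sums O1..O4 by default (O0 is
non-conducting); a config switch allows restricting conduction to O4
for sensitivity checks.

Occupancies evolve by the linear master equation ``dP/dt = Q^T P``;
the stepper uses a backward-Euler linear solve, which conserves total
probability exactly and is robust to the stiffness of the open-to-closed
rates at hyperpolarized potentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, IntegrationError

__all__ = [
    "STATE_NAMES",
    "BKParams",
    "BKState",
    "build_rate_matrix",
    "bk_step",
    "bk_steady_state",
    "bk_current",
]

STATE_NAMES: Tuple[str, ...] = (
    "C0", "C1", "C2", "C3", "C4", "O0", "O1", "O2", "O3", "O4",
)

#: Ca-binding multipliers along each ladder, transitions j -> j+1, j = 0..3
_LADDER_FWD = (3.0, 4.0, 3.0, 1.0)
#: Ca-unbinding multipliers, transitions j -> j-1, j = 1..4
_LADDER_BWD = (1.0, 3.0, 4.0, 3.0)


@dataclass(frozen=True)
class BKParams:
    """Rate constants and conductance of the 10-state BK scheme.

    ``co_rates``/``oc_rates`` are the base rates of the vertical C->O and
    O->C transitions for pair index 0..4, multiplied at run time by the
    voltage factors ``a`` and ``b`` respectively (the O4->C4 entry is
    further multiplied by cai).
    """

    gmax_s_cm2: float = 0.0008
    e_k_mv: float = -75.0
    k_on: float = 335.0
    k_coff: float = 26.0
    k_ooff: float = 26.0
    co_rates: Tuple[float, ...] = (
        0.03162, 0.000969, 0.0000381, 0.000881, 0.054324,
    )
    oc_rates: Tuple[float, ...] = (
        328.1084, 154.1736, 33.6594, 0.097312, 0.000406,
    )
    a_efold_mv: float = 25.0
    b_efold_mv: float = 25.0
    conducting_states: Tuple[str, ...] = ("O1", "O2", "O3", "O4")

    def __post_init__(self) -> None:
        if self.gmax_s_cm2 < 0.0:
            raise ConfigurationError("bk.gmax_s_cm2 must be >= 0 S/cm2")
        for name in ("k_on", "k_coff", "k_ooff"):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"bk.{name} must be >= 0")
        if len(self.co_rates) != 5 or len(self.oc_rates) != 5:
            raise ConfigurationError(
                "bk.co_rates and bk.oc_rates need exactly five entries"
            )
        if any(r < 0.0 for r in self.co_rates + self.oc_rates):
            raise ConfigurationError("bk vertical rates must be >= 0")
        if self.a_efold_mv <= 0.0 or self.b_efold_mv <= 0.0:
            raise ConfigurationError("bk e-fold slopes must be > 0 mV")
        unknown = set(self.conducting_states) - set(STATE_NAMES[5:])
        if unknown:
            raise ConfigurationError(
                f"bk.conducting_states must be open states, got {sorted(unknown)}"
            )

    @property
    def conducting_index(self) -> Tuple[int, ...]:
        return tuple(STATE_NAMES.index(s) for s in self.conducting_states)


@dataclass(frozen=True)
class BKState:
    """Occupancy probabilities over (C0..C4, O0..O4)."""

    occupancy: Tuple[float, ...]

    def __post_init__(self) -> None:
        occ = self.occupancy
        if len(occ) != 10:
            raise ConfigurationError("BK occupancy must have 10 entries")
        if any(p < -1e-12 or p > 1.0 + 1e-12 for p in occ):
            raise ConfigurationError("BK occupancies must lie in [0, 1]")
        if abs(sum(occ) - 1.0) > 1e-6:
            raise ConfigurationError("BK occupancies must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.occupancy, dtype=float)


def structure_matrices(
    params: BKParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Constant off-diagonal templates (L, CO, OC, OC4), each 10x10 with
    rows = source state, such that the off-diagonal rate matrix is

        R(v, cai) = cai*L + a*CO + b*OC + b*cai*OC4.
    """
    L = np.zeros((10, 10))
    CO = np.zeros((10, 10))
    OC = np.zeros((10, 10))
    OC4 = np.zeros((10, 10))
    for base, k_off in ((0, params.k_coff), (5, params.k_ooff)):
        for j in range(4):
            L[base + j, base + j + 1] = _LADDER_FWD[j] * params.k_on
        for j in range(1, 5):
            L[base + j, base + j - 1] = _LADDER_BWD[j - 1] * k_off
    for i in range(5):
        CO[i, 5 + i] = params.co_rates[i]
    for i in range(4):
        OC[5 + i, i] = params.oc_rates[i]
    OC4[9, 4] = params.oc_rates[4]
    return L, CO, OC, OC4


def voltage_factors(params: BKParams, v: float) -> Tuple[float, float]:
    """Opening factor ``a = exp(v/a_efold)`` and closing factor
    ``b = exp(-v/b_efold)``."""
    return float(np.exp(v / params.a_efold_mv)), float(np.exp(-v / params.b_efold_mv))


def build_rate_matrix(params: BKParams, v: float, cai: float) -> np.ndarray:
    """Generator matrix Q (1/ms), rows = source state, rows sum to zero.

    Off-diagonals hold the transition rates at membrane potential ``v``
    (mV) and Ca2+ concentration ``cai`` (mM); the diagonal is minus the
    row sum.  At cai = 0 every ladder (and the O4->C4) rate vanishes and
    the scheme decouples into five C<->O pairs.
    """
    if cai < 0.0:
        raise ConfigurationError(f"cai must be >= 0 mM, got {cai!r}")
    L, CO, OC, OC4 = structure_matrices(params)
    a, b = voltage_factors(params, v)
    Q = cai * L + a * CO + b * OC + (b * cai) * OC4
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(10)] = -Q.sum(axis=1)
    return Q


def bk_step(
    state: BKState, params: BKParams, v: float, cai: float, dt: float
) -> BKState:
    """Advance the occupancy one backward-Euler step at frozen (v, cai).

    Solves ``(I - dt*Q^T) p' = p``; because the columns of Q^T sum to
    zero the solve preserves total probability exactly.
    """
    if dt <= 0.0:
        raise ConfigurationError(f"dt must be > 0 ms, got {dt!r}")
    Q = build_rate_matrix(params, v, cai)
    p = state.as_array()
    M = np.eye(10) - dt * Q.T
    try:
        p_new = np.linalg.solve(M, p)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - proper generator
        raise IntegrationError(f"BK backward-Euler solve failed: {exc}") from exc
    p_new = np.clip(p_new, 0.0, None)
    p_new /= p_new.sum()
    return BKState(tuple(p_new))


def bk_steady_state(params: BKParams, v: float, cai: float) -> BKState:
    """Stationary occupancy: normalized null vector of the generator.

    Requires ``cai > 0``; at cai = 0 the chain splits into disconnected
    communicating classes and the stationary distribution is not unique.
    """
    if cai <= 0.0:
        raise ConfigurationError(
            "bk_steady_state needs cai > 0 mM; at cai = 0 the chain is "
            "reducible and has no unique stationary distribution"
        )
    Q = build_rate_matrix(params, v, cai)
    ns = scipy.linalg.null_space(Q.T, rcond=1e-12)
    if ns.shape[1] != 1:
        raise IntegrationError(
            f"BK generator null space has dimension {ns.shape[1]}, expected 1"
        )
    p = ns[:, 0]
    p = np.abs(p)
    p /= p.sum()
    return BKState(tuple(p))


def bk_current(params: BKParams, state: BKState, v: float) -> float:
    """BK current density in uA/cm2: ``gmax * O * (v - E_K)`` with ``O``
    summed over the configured conducting open states (O1..O4 by
    default)."""
    occ = state.as_array()
    o_sum = float(occ[list(params.conducting_index)].sum())
    return params.gmax_s_cm2 * o_sum * (v - params.e_k_mv) * 1e3
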