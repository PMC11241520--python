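"""Whole-cell assembly and time integration.

The cell is a parallel-conductance membrane: the specific capacitance in
parallel with the nine Hodgkin-Huxley-type conductances, the Markov BK
channel, the Ca2+-activated TRPM4 conductance and the ohmic leak, each
in series with its reversal potential.  The membrane equation in current
densities (uA/cm2, outward positive) is

    C_m dV/dt = -(sum_i I_i(V, gates)) + I_inj / A

integrated with an operator-split step at fixed dt (default 0.04 ms):

1. the Ca2+ pool advances using the Ca2+ channel currents at the current
   state (exact exponential update);
2. every HH/TRPM4 gate relaxes toward its steady state at the frozen
   voltage and the fresh Ca2+ concentration (exponential integrator,
   exact at frozen V);
3. the BK occupancies advance by a backward-Euler linear solve;
4. the voltage advances by backward Euler on the membrane equation,
   which is linear in V once the gates are frozen, making the update
   unconditionally stable.

The integration is fully deterministic: identical inputs give
bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from . import bk as bk_mod
from .bk import BKParams, BKState
from .calcium import CaPoolParams, ca_step
from .errors import ConfigurationError, IntegrationError
from .gating import GateParams, HHChannelSpec, TauTable, gate_inf, gate_tau
from .geometry import (
    CellGeometry,
    PassiveProperties,
    lateral_area,
)
from .stimuli import AlphaSynapse, PulseStimulus, alpha_conductance, pulse_current
from .trpm4 import TRPM4Params

__all__ = [
    "CellModel",
    "CellState",
    "SimulationResult",
    "Stimulus",
    "initial_state",
    "resting_state",
    "total_membrane_current",
    "step",
    "run",
    "scale_gmax",
    "with_gmax",
]

Stimulus = Union[None, PulseStimulus, AlphaSynapse]

_V_DIVERGE_MV = 200.0


@dataclass(frozen=True)
class CellModel:
    """Complete single-compartment cell: geometry, passive membrane,
    HH channel bank (including the ohmic leak), BK, TRPM4 and the Ca2+
    pool."""

    geometry: CellGeometry
    passive: PassiveProperties
    hh_channels: Tuple[HHChannelSpec, ...]
    bk: BKParams
    trpm4: TRPM4Params
    ca_pool: CaPoolParams

    def __post_init__(self) -> None:
        names = [c.name for c in self.hh_channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate channel names in {names}")
        for reserved in ("bk", "trpm4"):
            if reserved in names:
                raise ConfigurationError(
                    f"channel name {reserved!r} is reserved"
                )

    @property
    def area_cm2(self) -> float:
        return lateral_area(self.geometry)

    def channel(self, name: str) -> HHChannelSpec:
        for c in self.hh_channels:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class CellState:
    """Instantaneous state: voltage, gate values per channel, BK
    occupancy and intracellular Ca2+."""

    v_mv: float
    gates: Dict[str, Tuple[Optional[float], Optional[float]]]
    bk_state: BKState
    cai_mm: float
    t_ms: float = 0.0


@dataclass
class SimulationResult:
    """Trajectory on a uniform time grid.

    ``currents`` maps channel name (HH names plus ``bk`` and ``trpm4``)
    to current-density traces in uA/cm2, evaluated at the stored states.
    """

    t_ms: np.ndarray
    v_mv: np.ndarray
    cai_mm: np.ndarray
    currents: Dict[str, np.ndarray] = field(default_factory=dict)
    dt_ms: float = 0.04

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if len(self.v_mv) != n or len(self.cai_mm) != n:
            raise ConfigurationError("trace arrays must have equal length")

    def as_dataframe(self):
        import pandas as pd

        data = {"t_ms": self.t_ms, "v_mv": self.v_mv, "cai_mm": self.cai_mm}
        for name, tr in self.currents.items():
            data[f"i_{name}_ua_cm2"] = tr
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# compiled representation


class _Compiled:
    """Flat array view of a CellModel for the inner integration loop."""

    def __init__(self, model: CellModel) -> None:
        self.model = model
        self.area = model.area_cm2
        self.cm = model.passive.cm_uf_per_cm2

        chans = list(model.hh_channels)
        self.names = [c.name for c in chans] + ["trpm4"]
        n_ch = len(self.names)
        self.gmax = np.zeros(n_ch)
        self.erev = np.zeros(n_ch)
        self.is_ca = np.zeros(n_ch, dtype=bool)

        gates: list[GateParams] = []
        self.gate_names: list[Tuple[str, str]] = []
        act_idx = np.full(n_ch, -1, dtype=int)
        inact_idx = np.full(n_ch, -1, dtype=int)
        for i, c in enumerate(chans):
            self.gmax[i] = c.gmax_s_cm2 * c.open_fraction
            self.erev[i] = c.e_rev_mv
            self.is_ca[i] = c.is_calcium
            if c.activation is not None:
                act_idx[i] = len(gates)
                gates.append(c.activation)
                self.gate_names.append((c.name, "m"))
            if c.inactivation is not None:
                inact_idx[i] = len(gates)
                gates.append(c.inactivation)
                self.gate_names.append((c.name, "h"))
        # TRPM4 joins the generic gate bank as a purely Ca-gated channel
        tp = model.trpm4
        self.gmax[n_ch - 1] = tp.gmax_s_cm2
        self.erev[n_ch - 1] = tp.e_rev_mv
        act_idx[n_ch - 1] = len(gates)
        gates.append(
            GateParams(
                tau_ms=tp.tau_m_ms,
                power=tp.power,
                ca_half_mm=tp.ca_half_mm,
                hill_n=tp.hill_n,
            )
        )
        self.gate_names.append(("trpm4", "m"))

        self.act_idx = act_idx
        self.inact_idx = inact_idx
        self.gates = gates
        ng = len(gates)
        self.n_gates = ng
        self.vh = np.array(
            [g.v_half_mv if g.has_voltage else 0.0 for g in gates]
        )
        self.slope = np.array(
            [g.slope_mv if g.has_voltage else 1.0 for g in gates]
        )
        self.has_v = np.array([g.has_voltage for g in gates])
        self.cah_log = np.array(
            [math.log(g.ca_half_mm) if g.has_calcium else 0.0 for g in gates]
        )
        self.hn = np.array([g.hill_n if g.has_calcium else 1.0 for g in gates])
        self.has_ca = np.array([g.has_calcium for g in gates])
        self.power = np.array([float(g.power) for g in gates])
        self.tau_const = np.array(
            [
                g.tau_ms if not isinstance(g.tau_ms, TauTable) else np.nan
                for g in gates
            ]
        )
        self.tau_tables = [
            (k, g.tau_ms)
            for k, g in enumerate(gates)
            if isinstance(g.tau_ms, TauTable)
        ]
        self.act_pow = np.where(act_idx >= 0, self.power[np.maximum(act_idx, 0)], 0.0)
        self.inact_pow = np.where(
            inact_idx >= 0, self.power[np.maximum(inact_idx, 0)], 0.0
        )

        # BK structure (transposed so dP/dt = A @ p)
        L, CO, OC, OC4 = bk_mod.structure_matrices(model.bk)
        self.bk_stack = np.stack([m.T.copy() for m in (L, CO, OC, OC4)])
        self.bk_cond = np.array(model.bk.conducting_index, dtype=int)
        self.eye10 = np.eye(10)

    # -- elementary evaluations ------------------------------------------

    def gate_inf_tau(self, v: float, cai: float) -> Tuple[np.ndarray, np.ndarray]:
        arg = np.clip((v + self.vh) / self.slope, -60.0, 60.0)
        boltz = np.where(self.has_v, 1.0 / (1.0 + np.exp(arg)), 1.0)
        if cai > 0.0:
            harg = np.clip(self.hn * (self.cah_log - math.log(cai)), -600, 600)
            hill = np.where(self.has_ca, 1.0 / (1.0 + np.exp(harg)), 1.0)
        else:
            hill = np.where(self.has_ca, 0.0, 1.0)
        tau = self.tau_const.copy()
        for k, table in self.tau_tables:
            tau[k] = table(v)
        return boltz * hill, tau

    def conductances(self, gate_vals: np.ndarray) -> np.ndarray:
        """Per-channel open conductance densities, S/cm2."""
        act = np.where(
            self.act_idx >= 0,
            gate_vals[np.maximum(self.act_idx, 0)] ** self.act_pow,
            1.0,
        )
        inact = np.where(
            self.inact_idx >= 0,
            gate_vals[np.maximum(self.inact_idx, 0)] ** self.inact_pow,
            1.0,
        )
        return self.gmax * act * inact

    def bk_generator_t(self, v: float, cai: float) -> np.ndarray:
        """Q^T at (v, cai), 1/ms."""
        a, b = bk_mod.voltage_factors(self.model.bk, v)
        coef = np.array([cai, a, b, b * cai])
        A = np.tensordot(coef, self.bk_stack, axes=1)
        np.fill_diagonal(A, 0.0)
        A[np.diag_indices(10)] = -A.sum(axis=0)
        return A

    def bk_open_prob(self, bk_p: np.ndarray) -> float:
        return float(bk_p[self.bk_cond].sum())

    def stim_terms(
        self, t: float, v_ignored: float, stimulus: Stimulus
    ) -> Tuple[float, float, float]:
        """(injected density uA/cm2, synaptic conductance density S/cm2,
        synaptic reversal mV) at time t."""
        if stimulus is None:
            return 0.0, 0.0, 0.0
        if isinstance(stimulus, PulseStimulus):
            inj_na = pulse_current(t, stimulus)
            return inj_na * 1e-3 / self.area, 0.0, 0.0
        if isinstance(stimulus, AlphaSynapse):
            g_us = alpha_conductance(t, stimulus)
            return 0.0, g_us * 1e-6 / self.area, stimulus.e_syn_mv
        raise ConfigurationError(f"unknown stimulus type {type(stimulus)!r}")

    # -- one operator-split step -----------------------------------------

    def advance(
        self,
        v: float,
        gate_vals: np.ndarray,
        bk_p: np.ndarray,
        cai: float,
        t: float,
        stimulus: Stimulus,
        dt: float,
    ) -> Tuple[float, np.ndarray, np.ndarray, float]:
        # (1) Ca2+ pool from the Ca2+ channel currents at the current state
        g = self.conductances(gate_vals)
        i_ca = float((g[self.is_ca] * (v - self.erev[self.is_ca])).sum()) * 1e3
        cai_new = ca_step(cai, i_ca, self.model.ca_pool, dt)

        # (2) gates at frozen voltage, fresh calcium
        m_inf, tau = self.gate_inf_tau(v, cai_new)
        gate_new = m_inf + (gate_vals - m_inf) * np.exp(-dt / tau)

        # (3) BK occupancies, backward Euler
        A = self.bk_generator_t(v, cai_new)
        bk_new = np.linalg.solve(self.eye10 - dt * A, bk_p)
        bk_new = np.clip(bk_new, 0.0, None)
        bk_new /= bk_new.sum()

        # (4) voltage, backward Euler on the linearized membrane equation
        g = self.conductances(gate_new)
        g_bk = self.model.bk.gmax_s_cm2 * self.bk_open_prob(bk_new)
        inj, g_syn, e_syn = self.stim_terms(t, v, stimulus)
        g_tot = float(g.sum()) + g_bk + g_syn
        ge_tot = (
            float((g * self.erev).sum())
            + g_bk * self.model.bk.e_k_mv
            + g_syn * e_syn
        )
        k = dt / self.cm * 1e3  # (ms / (uF/cm2)) * (S/cm2*mV -> uA/cm2)
        v_new = (v + k * ge_tot + dt / self.cm * inj) / (1.0 + k * g_tot)
        if not math.isfinite(v_new) or abs(v_new) > _V_DIVERGE_MV:
            raise IntegrationError(
                f"membrane potential diverged (v = {v_new!r} mV) at "
                f"t = {t + dt:.3f} ms"
            )
        return v_new, gate_new, bk_new, cai_new

    def current_densities(
        self, v: float, gate_vals: np.ndarray, bk_p: np.ndarray
    ) -> np.ndarray:
        g = self.conductances(gate_vals)
        out = g * (v - self.erev) * 1e3
        i_bk = (
            self.model.bk.gmax_s_cm2
            * self.bk_open_prob(bk_p)
            * (v - self.model.bk.e_k_mv)
            * 1e3
        )
        return np.append(out, i_bk)

    # -- state packing ----------------------------------------------------

    def pack(self, state: CellState) -> Tuple[float, np.ndarray, np.ndarray, float]:
        vals = np.zeros(self.n_gates)
        for k, (cname, which) in enumerate(self.gate_names):
            pair = state.gates[cname]
            vals[k] = pair[0] if which == "m" else pair[1]
        return state.v_mv, vals, state.bk_state.as_array(), state.cai_mm

    def unpack(
        self,
        v: float,
        gate_vals: np.ndarray,
        bk_p: np.ndarray,
        cai: float,
        t: float,
    ) -> CellState:
        gates: Dict[str, Tuple[Optional[float], Optional[float]]] = {}
        for i, name in enumerate(self.names):
            m = (
                float(gate_vals[self.act_idx[i]])
                if self.act_idx[i] >= 0
                else None
            )
            h = (
                float(gate_vals[self.inact_idx[i]])
                if self.inact_idx[i] >= 0
                else None
            )
            gates[name] = (m, h)
        return CellState(
            v_mv=float(v),
            gates=gates,
            bk_state=BKState(tuple(bk_p)),
            cai_mm=float(cai),
            t_ms=float(t),
        )


@lru_cache(maxsize=32)
def _compile(model: CellModel) -> _Compiled:
    return _Compiled(model)


# ---------------------------------------------------------------------------
# public operations


def initial_state(
    model: CellModel,
    v0_mv: float = -52.0,
    cai0_mm: Optional[float] = None,
    equilibrate: bool = True,
) -> CellState:
    """Initial state at voltage ``v0_mv``.

    With ``equilibrate`` every gate sits at its steady state for
    (v0, cai0) and the BK occupancy at its stationary distribution, so an
    unstimulated run shows no initial transient beyond the slow drift to
    the true resting point.  Without it, gates start closed and the BK
    channel in C0, reproducing the initial fluctuation of a cold-started
    model.
    """
    c = _compile(model)
    cai = model.ca_pool.ca_rest_mm if cai0_mm is None else cai0_mm
    if equilibrate:
        m_inf, _ = c.gate_inf_tau(v0_mv, cai)
        bk_p = bk_mod.bk_steady_state(model.bk, v0_mv, cai).as_array()
    else:
        m_inf = np.zeros(c.n_gates)
        bk_p = np.zeros(10)
        bk_p[0] = 1.0
    return c.unpack(v0_mv, m_inf, bk_p, cai, 0.0)


def _self_consistent_cai(c: _Compiled, v: float) -> float:
    """Resting cai at voltage v: influx from steady-state Ca2+ channel
    currents balanced against extrusion (fixed-point iteration)."""
    pool = c.model.ca_pool
    cai = pool.ca_rest_mm
    if pool.clamp:
        return cai
    for _ in range(200):
        m_inf, _ = c.gate_inf_tau(v, cai)
        g = c.conductances(m_inf)
        i_ca = float((g[c.is_ca] * (v - c.erev[c.is_ca])).sum()) * 1e3
        cai_new = pool.ca_rest_mm - i_ca * pool.current_to_flux * pool.tau_removal_ms
        cai_new = max(cai_new, 1e-9)
        if abs(cai_new - cai) < 1e-15:
            return cai_new
        cai = 0.5 * cai + 0.5 * cai_new
    return cai


def resting_state(
    model: CellModel, v_lo: float = -90.0, v_hi: float = -20.0
) -> CellState:
    """True resting fixed point: solves dV/dt = 0 with every gate at its
    steady state and the Ca2+ pool self-consistent.  Raises
    :class:`IntegrationError` if no zero crossing lies in [v_lo, v_hi]."""
    c = _compile(model)

    def dvdt(v: float) -> float:
        cai = _self_consistent_cai(c, v)
        m_inf, _ = c.gate_inf_tau(v, cai)
        g = c.conductances(m_inf)
        bk_p = bk_mod.bk_steady_state(model.bk, v, cai).as_array()
        g_bk = model.bk.gmax_s_cm2 * c.bk_open_prob(bk_p)
        i = float((g * (v - c.erev)).sum()) * 1e3 + g_bk * (v - model.bk.e_k_mv) * 1e3
        return -i / c.cm

    f_lo, f_hi = dvdt(v_lo), dvdt(v_hi)
    if f_lo * f_hi > 0:
        raise IntegrationError(
            f"no resting point bracketed in [{v_lo}, {v_hi}] mV "
            f"(dV/dt = {f_lo:.3g}, {f_hi:.3g} mV/ms)"
        )
    v_rest = brentq(dvdt, v_lo, v_hi, xtol=1e-10)
    cai = _self_consistent_cai(c, v_rest)
    m_inf, _ = c.gate_inf_tau(v_rest, cai)
    bk_p = bk_mod.bk_steady_state(model.bk, v_rest, cai).as_array()
    return c.unpack(v_rest, m_inf, bk_p, cai, 0.0)


def total_membrane_current(
    model: CellModel, state: CellState, t: float, stimulus: Stimulus = None
) -> float:
    """Instantaneous dV/dt in mV/ms: all channel currents plus the
    stimulus, divided by the specific capacitance."""
    c = _compile(model)
    v, gate_vals, bk_p, _cai = c.pack(state)
    g = c.conductances(gate_vals)
    g_bk = model.bk.gmax_s_cm2 * c.bk_open_prob(bk_p)
    inj, g_syn, e_syn = c.stim_terms(t, v, stimulus)
    i_dens = (
        float((g * (v - c.erev)).sum()) * 1e3
        + g_bk * (v - model.bk.e_k_mv) * 1e3
        + g_syn * (v - e_syn) * 1e3
    )
    return (-i_dens + inj) / c.cm


def step(
    model: CellModel, state: CellState, stimulus: Stimulus, dt: float
) -> CellState:
    """Advance the state by one operator-split step of ``dt`` ms."""
    if dt <= 0.0:
        raise ConfigurationError(f"dt must be > 0 ms, got {dt!r}")
    c = _compile(model)
    v, gate_vals, bk_p, cai = c.pack(state)
    v, gate_vals, bk_p, cai = c.advance(
        v, gate_vals, bk_p, cai, state.t_ms, stimulus, dt
    )
    return c.unpack(v, gate_vals, bk_p, cai, state.t_ms + dt)


def run(
    model: CellModel,
    initial: Optional[CellState] = None,
    stimulus: Stimulus = None,
    t_stop_ms: float = 2000.0,
    dt_ms: float = 0.04,
    record_currents: bool = True,
) -> SimulationResult:
    """Integrate from t = 0 to ``t_stop_ms`` and return the trajectory.

    The grid has ``round(t_stop/dt) + 1`` points including t = 0.  The
    default initial state is the equilibrated state at -52 mV.
    """
    if t_stop_ms <= 0.0:
        raise ConfigurationError("t_stop_ms must be > 0 ms")
    if dt_ms <= 0.0:
        raise ConfigurationError("dt_ms must be > 0 ms")
    c = _compile(model)
    if initial is None:
        initial = initial_state(model)
    v, gate_vals, bk_p, cai = c.pack(initial)
    n = int(round(t_stop_ms / dt_ms))
    t_grid = np.arange(n + 1) * dt_ms
    v_tr = np.empty(n + 1)
    cai_tr = np.empty(n + 1)
    cur_tr = np.empty((n + 1, len(c.names) + 1)) if record_currents else None
    v_tr[0], cai_tr[0] = v, cai
    if record_currents:
        cur_tr[0] = c.current_densities(v, gate_vals, bk_p)
    for k in range(n):
        v, gate_vals, bk_p, cai = c.advance(
            v, gate_vals, bk_p, cai, float(t_grid[k]), stimulus, dt_ms
        )
        v_tr[k + 1] = v
        cai_tr[k + 1] = cai
        if record_currents:
            cur_tr[k + 1] = c.current_densities(v, gate_vals, bk_p)
    currents: Dict[str, np.ndarray] = {}
    if record_currents:
        for i, name in enumerate(c.names):
            currents[name] = cur_tr[:, i]
        currents["bk"] = cur_tr[:, -1]
    return SimulationResult(
        t_ms=t_grid, v_mv=v_tr, cai_mm=cai_tr, currents=currents, dt_ms=dt_ms
    )


# ---------------------------------------------------------------------------
# model editing helpers (used by sweeps, knockouts and calibration)


def with_gmax(model: CellModel, name: str, gmax_s_cm2: float) -> CellModel:
    """Copy of the model with one channel's maximum conductance replaced.

    ``name`` may be any HH channel name, ``"bk"`` or ``"trpm4"``.
    """
    import dataclasses

    if gmax_s_cm2 < 0.0:
        raise ConfigurationError("gmax_s_cm2 must be >= 0 S/cm2")
    if name == "bk":
        return dataclasses.replace(
            model, bk=dataclasses.replace(model.bk, gmax_s_cm2=gmax_s_cm2)
        )
    if name == "trpm4":
        return dataclasses.replace(
            model, trpm4=dataclasses.replace(model.trpm4, gmax_s_cm2=gmax_s_cm2)
        )
    found = False
    new_chans = []
    for ch in model.hh_channels:
        if ch.name == name:
            new_chans.append(dataclasses.replace(ch, gmax_s_cm2=gmax_s_cm2))
            found = True
        else:
            new_chans.append(ch)
    if not found:
        raise ConfigurationError(f"unknown channel {name!r}")
    return dataclasses.replace(model, hh_channels=tuple(new_chans))


def scale_gmax(model: CellModel, factors: Dict[str, float]) -> CellModel:
    """Copy of the model with channel conductances multiplied by the
    given per-channel factors."""
    out = model
    for name, f in factors.items():
        if f < 0.0:
            raise ConfigurationError("scale factors must be >= 0")
        if name == "bk":
            g0 = model.bk.gmax_s_cm2
        elif name == "trpm4":
            g0 = model.trpm4.gmax_s_cm2
        else:
            g0 = model.channel(name).gmax_s_cm2
        out = with_gmax(out, name, g0 * f)
    return out
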