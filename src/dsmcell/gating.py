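"""Generic Hodgkin-Huxley gating machinery.

Each voltage-gated conductance carries up to two gates (activation ``m``,
inactivation ``h``) obeying first-order kinetics

    dm/dt = (m_inf(V, Cai) - m) / tau_m

with a Boltzmann steady state

    m_inf(V) = 1 / (1 + exp((V + V_half) / S))

whose direction is set by the sign of the slope factor ``S``: activation
gates use a negative slope (increasing sigmoid), inactivation gates a
positive slope.  The sign is always explicit in the gate parameters; the
code never flips it silently.

Calcium-dependent gates (SK, IK, TRPM4-style) multiply the voltage factor
by a Hill function of the intracellular Ca2+ concentration,

    hill(Cai) = 1 / (1 + (Ca_half / Cai)^n),

and a gate may be purely Ca-dependent by omitting the voltage component.

Gates are advanced with the exponential integrator

    m' = m_inf + (m - m_inf) * exp(-dt / tau),

which is the exact solution of the relaxation ODE at frozen (V, Cai) and
therefore unconditionally stable at the simulator's 0.04 ms step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TauTable",
    "GateParams",
    "HHChannelSpec",
    "boltzmann_inf",
    "hill_activation",
    "gate_inf",
    "gate_tau",
    "gate_step",
    "hh_current",
]

_EXP_CLIP = 60.0  # exp argument clip; sigmoids saturate far before this


@dataclass(frozen=True)
class TauTable:
    """Voltage-indexed time-constant table (ms), linearly interpolated.

    Values outside the tabulated voltage range take the endpoint value.
    """

    v_mv: Tuple[float, ...]
    tau_ms: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.v_mv) != len(self.tau_ms) or len(self.v_mv) < 2:
            raise ConfigurationError(
                "tau table needs >= 2 matching (v_mv, tau_ms) pairs"
            )
        if any(t <= 0.0 for t in self.tau_ms):
            raise ConfigurationError("tau table values must be > 0 ms")
        if any(b <= a for a, b in zip(self.v_mv, self.v_mv[1:])):
            raise ConfigurationError("tau table voltages must be increasing")

    def __call__(self, v: float) -> float:
        return float(np.interp(v, self.v_mv, self.tau_ms))


@dataclass(frozen=True)
class GateParams:
    """Parameters of one first-order gate.

    At least one of the voltage component (``v_half_mv``/``slope_mv``) and
    the calcium component (``ca_half_mm``/``hill_n``) must be present; if
    both are, the steady state is their product.

    Attributes
    ----------
    v_half_mv : float or None
        Boltzmann half-potential offset V_half in mV; the sigmoid midpoint
        sits at V = -V_half.
    slope_mv : float or None
        Signed slope factor S in mV (negative: activation, positive:
        inactivation).
    tau_ms : float or TauTable
        Relaxation time constant (ms), constant or voltage-indexed.
    power : int
        Exponent applied to the gate in the current law.
    ca_half_mm : float or None
        Hill half-activation Ca2+ concentration, mM.
    hill_n : float or None
        Hill coefficient (dimensionless).
    """

    v_half_mv: Optional[float] = None
    slope_mv: Optional[float] = None
    tau_ms: Union[float, TauTable] = 1.0
    power: int = 1
    ca_half_mm: Optional[float] = None
    hill_n: Optional[float] = None

    def __post_init__(self) -> None:
        has_v = self.v_half_mv is not None or self.slope_mv is not None
        has_ca = self.ca_half_mm is not None or self.hill_n is not None
        if has_v and (self.v_half_mv is None or self.slope_mv is None):
            raise ConfigurationError(
                "gate voltage component needs both v_half_mv (mV) and slope_mv (mV)"
            )
        if has_ca and (self.ca_half_mm is None or self.hill_n is None):
            raise ConfigurationError(
                "gate calcium component needs both ca_half_mm (mM) and hill_n"
            )
        if not has_v and not has_ca:
            raise ConfigurationError(
                "gate needs a voltage and/or a calcium component"
            )
        if has_v and self.slope_mv == 0.0:
            raise ConfigurationError("gate slope_mv must be nonzero (mV)")
        if has_ca and not (self.ca_half_mm > 0.0 and self.hill_n > 0.0):
            raise ConfigurationError(
                "gate ca_half_mm (mM) and hill_n must be > 0"
            )
        if isinstance(self.tau_ms, (int, float)) and not (self.tau_ms > 0.0):
            raise ConfigurationError(
                f"gate tau_ms must be > 0 ms, got {self.tau_ms!r}"
            )
        if self.power < 0:
            raise ConfigurationError("gate power must be >= 0")

    @property
    def has_voltage(self) -> bool:
        return self.v_half_mv is not None

    @property
    def has_calcium(self) -> bool:
        return self.ca_half_mm is not None


@dataclass(frozen=True)
class HHChannelSpec:
    """One Hodgkin-Huxley-type conductance.

    ``is_calcium`` marks channels whose current feeds the intracellular
    Ca2+ pool (CaT, CaL).  ``open_fraction`` is a constant openness
    scale for channels gated by ligands outside the model's scope (the
    ATP-sensitive K+ channel: intracellular ATP is not modelled, so its
    tonic openness is a fixed calibrated fraction of gmax).
    """

    name: str
    gmax_s_cm2: float
    e_rev_mv: float
    activation: Optional[GateParams] = None
    inactivation: Optional[GateParams] = None
    is_calcium: bool = False
    open_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.gmax_s_cm2 < 0.0:
            raise ConfigurationError(
                f"channel {self.name!r}: gmax_s_cm2 must be >= 0 S/cm2"
            )
        if not (0.0 <= self.open_fraction <= 1.0):
            raise ConfigurationError(
                f"channel {self.name!r}: open_fraction must be in [0, 1]"
            )


def boltzmann_inf(v: float, gate: GateParams) -> float:
    """Boltzmann steady state ``1 / (1 + exp((v + v_half) / slope))``.

    Strictly monotone in ``v`` (direction set by the slope sign) and
    bounded in (0, 1); saturates smoothly at extreme voltages.
    """
    if not gate.has_voltage:
        raise ConfigurationError("gate has no voltage component")
    arg = (v + gate.v_half_mv) / gate.slope_mv
    arg = min(max(arg, -_EXP_CLIP), _EXP_CLIP)
    return 1.0 / (1.0 + math.exp(arg))


def hill_activation(cai: float, ca_half: float, n: float) -> float:
    """Hill steady state ``1 / (1 + (ca_half / cai)^n)``; 0 at cai <= 0."""
    if cai <= 0.0:
        return 0.0
    arg = n * (math.log(ca_half) - math.log(cai))
    arg = min(max(arg, -_EXP_CLIP * 10), _EXP_CLIP * 10)
    return 1.0 / (1.0 + math.exp(arg))


def gate_inf(v: float, gate: GateParams, cai: Optional[float] = None) -> float:
    """Full steady state: Boltzmann factor times Hill factor (if present)."""
    out = 1.0
    if gate.has_voltage:
        out *= boltzmann_inf(v, gate)
    if gate.has_calcium:
        if cai is None:
            raise ConfigurationError(
                "Ca-dependent gate evaluated without a cai value (mM)"
            )
        out *= hill_activation(cai, gate.ca_half_mm, gate.hill_n)
    return out


def gate_tau(v: float, gate: GateParams) -> float:
    """Time constant at voltage ``v`` (ms)."""
    tau = gate.tau_ms
    return tau(v) if isinstance(tau, TauTable) else float(tau)


def gate_step(
    m: float,
    v: float,
    gate: GateParams,
    dt: float,
    cai: Optional[float] = None,
) -> float:
    """Advance the gate one step with the exponential integrator.

    Exact for frozen (v, cai); the result stays in [0, 1] whenever the
    input does.
    """
    if dt <= 0.0:
        raise ConfigurationError(f"dt must be > 0 ms, got {dt!r}")
    tau = gate_tau(v, gate)
    if tau <= 0.0:
        raise ConfigurationError(f"gate tau must be > 0 ms, got {tau!r}")
    m_inf = gate_inf(v, gate, cai)
    return m_inf + (m - m_inf) * math.exp(-dt / tau)


def hh_current(
    spec: HHChannelSpec,
    m: Optional[float],
    h: Optional[float],
    v: float,
) -> float:
    """Ohmic channel current density in uA/cm2 (outward positive).

    ``gmax * m^x * h^y * (v - e_rev)``; gates absent from the spec are
    treated as unity.
    """
    g = spec.gmax_s_cm2 * spec.open_fraction
    if spec.activation is not None:
        if m is None:
            raise ConfigurationError(
                f"channel {spec.name!r}: activation gate value missing"
            )
        g *= m ** spec.activation.power
    if spec.inactivation is not None:
        if h is None:
            raise ConfigurationError(
                f"channel {spec.name!r}: inactivation gate value missing"
            )
        g *= h ** spec.inactivation.power
    # S/cm2 * mV = 1e-3 A/cm2 -> 1000 uA/cm2
    return g * (v - spec.e_rev_mv) * 1e3
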