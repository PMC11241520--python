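"""TRPM4: Ca2+-activated non-selective cation channel.

TRPM4 carries a depolarizing cation current gated by intracellular
Ca2+.  Its single activation gate relaxes with first-order kinetics

    dm/dt = (m_inf(Cai) - m) / tau_m

toward a Hill steady state

    m_inf(Cai) = 1 / (1 + (Ca_half / Cai)^n),

and the current is ohmic, ``I = gmax * m^x * (V - E_rev)`` with the
reversal potential set at -40 mV (mixed Na+/K+ conduction).  The model
uses a single activation gate (the steady state and the kinetic gate
are the same variable); no inactivation process is included by default.

``Ca_half`` and ``n`` are free parameters fitted against steady-state
activation data (see :mod:`dsmcell.fitting`).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import ConfigurationError
from .gating import hill_activation

__all__ = ["TRPM4Params", "hill_inf", "trpm4_gate_step", "trpm4_current"]


@dataclass(frozen=True)
class TRPM4Params:
    """TRPM4 conductance, reversal and Hill-activation parameters.

    Attributes
    ----------
    gmax_s_cm2 : float
        Maximum conductance density, S/cm2.
    e_rev_mv : float
        Reversal potential, mV (default -40).
    ca_half_mm : float
        Half-activation Ca2+ concentration, mM.
    hill_n : float
        Hill coefficient.
    tau_m_ms : float
        Activation time constant, ms.
    power : int
        Gate exponent in the current law.
    """

    gmax_s_cm2: float = 0.0002
    e_rev_mv: float = -40.0
    ca_half_mm: float = 4.0e-4
    hill_n: float = 2.0
    tau_m_ms: float = 10.0
    power: int = 1

    def __post_init__(self) -> None:
        if self.gmax_s_cm2 < 0.0:
            raise ConfigurationError("trpm4.gmax_s_cm2 must be >= 0 S/cm2")
        if not (self.ca_half_mm > 0.0):
            raise ConfigurationError("trpm4.ca_half_mm must be > 0 mM")
        if not (self.hill_n > 0.0):
            raise ConfigurationError("trpm4.hill_n must be > 0")
        if not (self.tau_m_ms > 0.0):
            raise ConfigurationError("trpm4.tau_m_ms must be > 0 ms")
        if self.power < 1:
            raise ConfigurationError("trpm4.power must be >= 1")


def hill_inf(cai: float, params: TRPM4Params) -> float:
    """Steady-state activation ``1 / (1 + (ca_half/cai)^n)``.

    Returns 0 at cai = 0 and increases strictly with cai; against
    log10(cai) it is a logistic with midpoint log10(ca_half).
    """
    return hill_activation(cai, params.ca_half_mm, params.hill_n)


def trpm4_gate_step(m: float, cai: float, params: TRPM4Params, dt: float) -> float:
    """Exponential relaxation of the activation gate toward
    ``hill_inf(cai)`` over one step of ``dt`` ms."""
    if dt <= 0.0:
        raise ConfigurationError(f"dt must be > 0 ms, got {dt!r}")
    m_inf = hill_inf(cai, params)
    return m_inf + (m - m_inf) * math.exp(-dt / params.tau_m_ms)


def trpm4_current(params: TRPM4Params, m: float, v: float) -> float:
    """TRPM4 current density in uA/cm2 (outward positive):
    ``gmax * m^power * (v - e_rev)``.  Inward (depolarizing) below the
    -40 mV reversal, hence depolarizing at rest."""
    return params.gmax_s_cm2 * m ** params.power * (v - params.e_rev_mv) * 1e3
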