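"""Minimal intracellular Ca2+ balance.

A single well-mixed submembrane shell receives Ca2+ influx from the
voltage-gated Ca2+ currents and relaxes back to a resting level with
first-order kinetics:

    d[Ca]/dt = -I_Ca / (2 F d (1 + kappa)) - ([Ca] - Ca_rest) / tau

where ``d`` is the shell depth, ``F`` the Faraday constant and ``kappa``
a rapid-buffering capacity (bound:free ratio) that scales down the free
concentration change.  Alternatively a direct current-to-concentration
factor (mM/ms per uA/cm2) may be supplied.  ``clamp`` mode pins the
concentration at the resting level, reproducing a strictly maintained
resting Ca2+ of 150 nM.

The update is the exact exponential step of the linear ODE at frozen
Ca2+ current, with a floor at 1e-9 mM (warned through the module
logger) so the concentration can never become non-positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError

__all__ = ["FARADAY_C_PER_MOL", "CaPoolParams", "ca_step"]

logger = logging.getLogger(__name__)

FARADAY_C_PER_MOL = 96485.33212
_CA_FLOOR_MM = 1e-9


@dataclass(frozen=True)
class CaPoolParams:
    """Parameters of the single-pool Ca2+ balance.

    Attributes
    ----------
    ca_rest_mm : float
        Resting (pump set-point) concentration, mM; default 150 nM.
    tau_removal_ms : float
        First-order extrusion time constant, ms.
    depth_um : float
        Effective submembrane shell depth, um.
    buffer_capacity : float
        Rapid-buffer capacity kappa (dimensionless); influx is divided
        by (1 + kappa).
    flux_factor : float or None
        Direct current-to-concentration factor, mM/ms per uA/cm2.  When
        given it overrides the shell/buffer computation.
    clamp : bool
        If true, the concentration is held at ``ca_rest_mm``.
    """

    ca_rest_mm: float = 1.5e-4
    tau_removal_ms: float = 20.0
    depth_um: float = 0.1
    buffer_capacity: float = 0.0
    flux_factor: Optional[float] = None
    clamp: bool = False

    def __post_init__(self) -> None:
        if not (self.ca_rest_mm > 0.0):
            raise ConfigurationError("calcium.ca_rest_mm must be > 0 mM")
        if not (self.tau_removal_ms > 0.0):
            raise ConfigurationError("calcium.tau_removal_ms must be > 0 ms")
        if not (self.depth_um > 0.0):
            raise ConfigurationError("calcium.depth_um must be > 0 um")
        if self.buffer_capacity < 0.0:
            raise ConfigurationError("calcium.buffer_capacity must be >= 0")
        if self.flux_factor is not None and not (self.flux_factor > 0.0):
            raise ConfigurationError(
                "calcium.flux_factor must be > 0 mM/ms per uA/cm2"
            )

    @property
    def current_to_flux(self) -> float:
        """mM/ms of free-Ca2+ rise per uA/cm2 of inward Ca2+ current."""
        if self.flux_factor is not None:
            return self.flux_factor
        depth_cm = self.depth_um * 1e-4
        # uA/cm2 -> A/cm2 (1e-6); / (2 F depth) -> mol s-1 cm-3;
        # -> mM/ms multiply by 1e6 * 1e-3 = 1e3; net 1e-3.
        return 1e-3 / (
            2.0 * FARADAY_C_PER_MOL * depth_cm * (1.0 + self.buffer_capacity)
        )


def ca_step(
    cai: float, i_ca_total: float, params: CaPoolParams, dt: float
) -> float:
    """Advance the Ca2+ concentration one step.

    Parameters
    ----------
    cai : float
        Current concentration, mM (> 0).
    i_ca_total : float
        Summed Ca2+ channel current density, uA/cm2, outward positive —
        an inward (negative) current raises the concentration.
    dt : float
        Step, ms.
    """
    if dt <= 0.0:
        raise ConfigurationError(f"dt must be > 0 ms, got {dt!r}")
    if params.clamp:
        return params.ca_rest_mm
    # d cai/dt = A - cai/tau, exact exponential update at frozen current
    tau = params.tau_removal_ms
    a = -i_ca_total * params.current_to_flux + params.ca_rest_mm / tau
    c_inf = a * tau
    new = c_inf + (cai - c_inf) * math.exp(-dt / tau)
    if new < _CA_FLOOR_MM:
        logger.warning(
            "cai floored at %.1e mM (outward Ca2+ current exceeded pool)",
            _CA_FLOOR_MM,
        )
        new = _CA_FLOOR_MM
    return new
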