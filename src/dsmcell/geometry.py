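"""Cylindrical cell geometry and passive membrane properties.

The detrusor smooth muscle (DSM) cell is represented as a single
electrical compartment with the morphology of an open cylinder
(end caps excluded, the usual single-compartment convention).
Specific passive constants are converted here into the absolute
quantities the membrane equation needs: lateral surface area,
total capacitance and leak conductance density.

Internal unit system: mV, ms, nA, pF, S/cm2, mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = [
    "CellGeometry",
    "PassiveProperties",
    "lateral_area",
    "total_capacitance",
    "leak_conductance_density",
]


@dataclass(frozen=True)
class CellGeometry:
    """Cylinder dimensions of the single-compartment cell.

    Attributes
    ----------
    length_um : float
        Cell length in micrometres.
    diameter_um : float
        Cell diameter in micrometres.
    """

    length_um: float = 200.0
    diameter_um: float = 6.0

    def __post_init__(self) -> None:
        if not (self.length_um > 0.0):
            raise ConfigurationError(
                f"geometry.length_um must be > 0 um, got {self.length_um!r}"
            )
        if not (self.diameter_um > 0.0):
            raise ConfigurationError(
                f"geometry.diameter_um must be > 0 um, got {self.diameter_um!r}"
            )


@dataclass(frozen=True)
class PassiveProperties:
    """Specific passive membrane constants.

    Attributes
    ----------
    cm_uf_per_cm2 : float
        Specific membrane capacitance, uF/cm2.
    rm_kohm_cm2 : float
        Specific membrane resistivity, kOhm*cm2 (sets the leak conductance).
    ra_ohm_cm : float
        Cytoplasmic resistivity, Ohm*cm.  Stored for config fidelity; a
        single compartment carries no axial current, so it is unused.
    e_leak_mv : float
        Reversal potential of the ohmic leak, mV.
    """

    cm_uf_per_cm2: float = 1.0
    rm_kohm_cm2: float = 138.0
    ra_ohm_cm: float = 183.0
    e_leak_mv: float = 0.0

    def __post_init__(self) -> None:
        for name, unit in (
            ("cm_uf_per_cm2", "uF/cm2"),
            ("rm_kohm_cm2", "kOhm*cm2"),
            ("ra_ohm_cm", "Ohm*cm"),
        ):
            value = getattr(self, name)
            if not (value > 0.0):
                raise ConfigurationError(
                    f"passive.{name} must be > 0 {unit}, got {value!r}"
                )


def lateral_area(geom: CellGeometry) -> float:
    """Lateral (open-cylinder) surface area in cm2.

    ``pi * diameter * length``, converted from um2 to cm2.  End caps are
    excluded.
    """
    return math.pi * geom.diameter_um * geom.length_um * 1e-8


def total_capacitance(geom: CellGeometry, passive: PassiveProperties) -> float:
    """Whole-cell membrane capacitance in pF.

    ``specific capacitance x lateral area``; 1 uF/cm2 over the default
    200 um x 6 um cylinder gives 37.7 pF.
    """
    # uF/cm2 * cm2 = uF; 1 uF = 1e6 pF
    return passive.cm_uf_per_cm2 * lateral_area(geom) * 1e6


def leak_conductance_density(passive: PassiveProperties) -> float:
    """Leak conductance density in S/cm2 (reciprocal membrane resistivity)."""
    return 1.0 / (passive.rm_kohm_cm2 * 1e3)
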