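"""Default model configuration.

The geometry, passive constants and maximum conductances carry the
``paper`` provenance tag: they are the published values of the DSM cell
model (cylinder 200 um x 6 um; Rm 138 kOhm*cm2; Ra 183 Ohm*cm; Cm
1 uF/cm2; the per-channel gmax table).  Gating kinetics (half-potentials,
slopes, time constants), the BK voltage-factor e-fold slopes, the TRPM4
Hill parameters, the Ca2+-pool constants, the leak reversal and the
stimulus unit scale are ``calibrated``: free parameters of this package,
tuned once with the bounded calibration routine so that the assembled
cell reproduces the published whole-cell behaviour (resting membrane
potential -52 mV; 10-ms pulse threshold 0.56 stimulus units; synaptic
threshold 0.0079 uS; AP threshold voltage near -38.5 mV).  Everything
else is ``default`` plumbing.

Channel sign conventions: activation gates use negative Boltzmann
slopes, inactivation gates positive ones; E_K = -75 mV, fixed Ca2+
reversal +50 mV, TRPM4 reversal -40 mV.
"""

from __future__ import annotations

import copy
from typing import Any, Dict

__all__ = ["default_config", "PROVENANCE", "UNITS"]


_DEFAULT_CONFIG: Dict[str, Any] = {
    "geometry": {"length_um": 200.0, "diameter_um": 6.0},
    "passive": {
        "cm_uf_per_cm2": 1.0,
        "rm_kohm_cm2": 138.0,
        "ra_ohm_cm": 183.0,
        "e_leak_mv": 50.0,
    },
    "channels": {
        "cat": {
            "gmax_s_cm2": 0.0002,
            "e_rev_mv": 50.0,
            "is_calcium": True,
            "activation": {
                "v_half_mv": 39.5, "slope_mv": -2.0, "tau_ms": 1.5, "power": 1,
            },
            "inactivation": {
                "v_half_mv": 47.0, "slope_mv": 7.0, "tau_ms": 100.0, "power": 1,
            },
        },
        "cal": {
            "gmax_s_cm2": 0.0003,
            "e_rev_mv": 50.0,
            "is_calcium": True,
            "activation": {
                "v_half_mv": 34.0, "slope_mv": -3.5, "tau_ms": 1.0, "power": 1,
            },
            "inactivation": {
                "v_half_mv": 46.0, "slope_mv": 9.0, "tau_ms": 80.0, "power": 1,
            },
        },
        "kv1": {
            "gmax_s_cm2": 0.0006,
            "e_rev_mv": -70.0,
            "activation": {
                "v_half_mv": 47.4, "slope_mv": -2.0, "tau_ms": 3.0, "power": 1,
            },
            "inactivation": {
                "v_half_mv": 40.0, "slope_mv": 2.5, "tau_ms": 3.5, "power": 1,
            },
        },
        "kdr": {
            "gmax_s_cm2": 0.0009,
            "e_rev_mv": -70.0,
            "activation": {
                "v_half_mv": 18.0, "slope_mv": -8.0, "tau_ms": 10.0, "power": 1,
            },
        },
        "kir": {
            "gmax_s_cm2": 0.0001,
            "e_rev_mv": -70.0,
            "activation": {
                "v_half_mv": 75.0, "slope_mv": 8.0, "tau_ms": 1.0, "power": 1,
            },
        },
        "katp": {
            "gmax_s_cm2": 0.0001,
            "e_rev_mv": -70.0,
            "open_fraction": 0.35,
        },
        "sk": {
            "gmax_s_cm2": 0.0001,
            "e_rev_mv": -70.0,
            "activation": {
                "ca_half_mm": 1.2e-3, "hill_n": 4.0, "tau_ms": 15.0, "power": 1,
            },
        },
        "ik": {
            "gmax_s_cm2": 0.0007,
            "e_rev_mv": -70.0,
            "activation": {
                "ca_half_mm": 1.2e-3, "hill_n": 4.0, "tau_ms": 15.0, "power": 1,
            },
        },
        "bk": {
            "gmax_s_cm2": 0.0008,
            "e_k_mv": -70.0,
            "k_on": 335.0,
            "k_coff": 26.0,
            "k_ooff": 26.0,
            "co_rates": [0.03162, 0.000969, 0.0000381, 0.000881, 0.054324],
            "oc_rates": [328.1084, 154.1736, 33.6594, 0.097312, 0.000406],
            "a_efold_mv": 12.0,
            "b_efold_mv": 25.0,
            "conducting_states": ["O1", "O2", "O3", "O4"],
        },
        "trpm4": {
            "gmax_s_cm2": 0.0002,
            "e_rev_mv": -40.0,
            "ca_half_mm": 9.4455e-05,
            "hill_n": 2.0,
            "tau_m_ms": 10.0,
            "power": 1,
        },
    },
    "calcium": {
        "ca_rest_mm": 1.5e-4,
        "tau_removal_ms": 20.0,
        "depth_um": 0.1,
        "buffer_capacity": 400.0,
        "clamp": False,
    },
    "stimulus": {
        "kind": "pulse",
        "amplitude": 0.56,
        "unit_na": 0.4988,
        "onset_ms": 150.0,
        "duration_ms": 10.0,
        "g_peak_us": 0.0079,
        "tau_alpha_ms": 7.5,
        "e_syn_mv": 0.0,
    },
    "run": {
        "dt_ms": 0.04,
        "t_stop_ms": 2000.0,
        "settle_ms": 500.0,
        "v_init_mv": -52.0,
        "equilibrate": True,
    },
    "experiments": {
        "threshold_t_stop_ms": 450.0,
        "sweep_amplitude": 0.8,
        "sweep_factors": [0.7, 0.8, 0.9, 1.0, 1.1, 1.2],
        "knockout_mute": "cat",
        "knockout_compensation": {
            "trpm4": 0.0003, "cal": 0.0009, "kir": 0.00005,
        },
    },
}


#: provenance tag per top-level parameter group or dotted path:
#: ``paper`` (published value), ``calibrated`` (tuned free parameter of
#: this package) or ``default`` (plumbing choice).
PROVENANCE: Dict[str, str] = {
    "geometry": "paper",
    "passive.cm_uf_per_cm2": "paper",
    "passive.rm_kohm_cm2": "paper",
    "passive.ra_ohm_cm": "paper",
    "passive.e_leak_mv": "calibrated",
    "channels.*.gmax_s_cm2": "paper",
    "channels.*.activation": "calibrated",
    "channels.*.inactivation": "calibrated",
    "channels.*.e_rev_mv": "calibrated",
    "channels.bk.k_on": "paper",
    "channels.bk.k_coff": "paper",
    "channels.bk.k_ooff": "paper",
    "channels.bk.co_rates": "paper",
    "channels.bk.oc_rates": "paper",
    "channels.bk.a_efold_mv": "calibrated",
    "channels.bk.b_efold_mv": "calibrated",
    "channels.trpm4.e_rev_mv": "paper",
    "channels.trpm4.ca_half_mm": "calibrated",
    "channels.trpm4.hill_n": "calibrated",
    "channels.trpm4.tau_m_ms": "calibrated",
    "calcium.ca_rest_mm": "paper",
    "calcium.tau_removal_ms": "calibrated",
    "calcium.depth_um": "calibrated",
    "calcium.buffer_capacity": "calibrated",
    "stimulus.unit_na": "calibrated",
    "run.dt_ms": "paper",
    "run.t_stop_ms": "paper",
    "run.settle_ms": "paper",
    "run.v_init_mv": "paper",
}

#: unit string per config field name (used in validation errors)
UNITS: Dict[str, str] = {
    "length_um": "um",
    "diameter_um": "um",
    "cm_uf_per_cm2": "uF/cm2",
    "rm_kohm_cm2": "kOhm*cm2",
    "ra_ohm_cm": "Ohm*cm",
    "e_leak_mv": "mV",
    "gmax_s_cm2": "S/cm2",
    "e_rev_mv": "mV",
    "e_k_mv": "mV",
    "v_half_mv": "mV",
    "slope_mv": "mV",
    "tau_ms": "ms",
    "power": "dimensionless",
    "ca_half_mm": "mM",
    "hill_n": "dimensionless",
    "tau_m_ms": "ms",
    "k_on": "1/(mM*ms)",
    "k_coff": "1/(mM*ms)",
    "k_ooff": "1/(mM*ms)",
    "co_rates": "1/ms",
    "oc_rates": "1/ms",
    "a_efold_mv": "mV",
    "b_efold_mv": "mV",
    "conducting_states": "state names",
    "is_calcium": "flag",
    "open_fraction": "dimensionless in [0,1]",
    "ca_rest_mm": "mM",
    "tau_removal_ms": "ms",
    "depth_um": "um",
    "buffer_capacity": "dimensionless",
    "flux_factor": "mM/ms per uA/cm2",
    "clamp": "flag",
    "kind": "pulse|alpha",
    "amplitude": "stimulus units",
    "unit_na": "nA per stimulus unit",
    "onset_ms": "ms",
    "duration_ms": "ms",
    "g_peak_us": "uS",
    "tau_alpha_ms": "ms",
    "e_syn_mv": "mV",
    "dt_ms": "ms",
    "t_stop_ms": "ms",
    "settle_ms": "ms",
    "v_init_mv": "mV",
    "equilibrate": "flag",
    "threshold_t_stop_ms": "ms",
    "sweep_amplitude": "stimulus units",
    "sweep_factors": "dimensionless",
    "knockout_mute": "channel name",
    "knockout_compensation": "channel -> S/cm2",
}


def default_config() -> Dict[str, Any]:
    """Deep copy of the shipped default configuration."""
    return copy.deepcopy(_DEFAULT_CONFIG)
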