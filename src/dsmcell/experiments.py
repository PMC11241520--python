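"""Canonical whole-cell experiments on the shipped model.

Thin, reusable drivers for the protocols the calibrated cell is
validated against: the 2000-ms resting-potential hold, the 10-ms pulse
and alpha-synapse threshold searches with their AP-threshold voltages,
the TRPM4 conductance sensitivity sweep, and the T-type knockout /
compensation experiment.  Both the test suite and the acceptance
script drive the model through these functions.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Dict, Optional, Tuple

import numpy as np

from .config import build_model
from .defaults import default_config
from .features import (
    APFeatures,
    SweepResult,
    conductance_sweep,
    extract_features,
    knockout_experiment,
    threshold_search,
)
from .simulator import CellModel, SimulationResult, initial_state, run
from .stimuli import AlphaSynapse, PulseStimulus

__all__ = [
    "default_model",
    "pulse_template",
    "alpha_template",
    "rmp_hold",
    "pulse_threshold",
    "alpha_threshold",
    "threshold_voltage",
    "trpm4_sweep",
    "cat_knockout",
]


def default_model(cfg: Optional[Dict[str, Any]] = None) -> Tuple[CellModel, Dict[str, Any]]:
    """The calibrated default cell model and its config dict."""
    cfg = cfg or default_config()
    return build_model(cfg), cfg


def pulse_template(cfg: Dict[str, Any], amplitude: float = 0.0) -> PulseStimulus:
    s = cfg["stimulus"]
    return PulseStimulus(
        amplitude=amplitude,
        onset_ms=s["onset_ms"],
        duration_ms=s["duration_ms"],
        unit_na=s["unit_na"],
    )


def alpha_template(cfg: Dict[str, Any], g_peak_us: float = 0.0) -> AlphaSynapse:
    s = cfg["stimulus"]
    return AlphaSynapse(
        g_peak_us=g_peak_us,
        tau_alpha_ms=s["tau_alpha_ms"],
        e_syn_mv=s["e_syn_mv"],
        onset_ms=s["onset_ms"],
    )


def rmp_hold(
    model: CellModel, cfg: Dict[str, Any], t_stop_ms: Optional[float] = None
) -> SimulationResult:
    """Unstimulated run over the configured duration (2000 ms)."""
    rs = cfg["run"]
    init = initial_state(model, v0_mv=rs["v_init_mv"], equilibrate=rs["equilibrate"])
    return run(
        model,
        initial=init,
        stimulus=None,
        t_stop_ms=t_stop_ms if t_stop_ms is not None else rs["t_stop_ms"],
        dt_ms=rs["dt_ms"],
        record_currents=False,
    )


def pulse_threshold(
    model: CellModel,
    cfg: Dict[str, Any],
    lo: float = 0.1,
    hi: float = 1.2,
    resolution: float = 0.01,
) -> float:
    """Minimal spiking 10-ms pulse amplitude (stimulus units) by
    bisection at the given grid resolution."""
    return threshold_search(
        model,
        pulse_template(cfg),
        lo,
        hi,
        resolution,
        t_stop_ms=cfg["experiments"]["threshold_t_stop_ms"],
        dt_ms=cfg["run"]["dt_ms"],
    )


def alpha_threshold(
    model: CellModel,
    cfg: Dict[str, Any],
    lo: float = 0.004,
    hi: float = 0.02,
    resolution: float = 0.0001,
) -> float:
    """Minimal spiking alpha-synapse peak conductance (uS)."""
    return threshold_search(
        model,
        alpha_template(cfg),
        lo,
        hi,
        resolution,
        t_stop_ms=cfg["experiments"]["threshold_t_stop_ms"],
        dt_ms=cfg["run"]["dt_ms"],
    )


def threshold_voltage(
    model: CellModel,
    cfg: Dict[str, Any],
    stimulus,
) -> APFeatures:
    """AP features (incl. threshold voltage) for a just-suprathreshold
    stimulus built from either template."""
    init = initial_state(model)
    res = run(
        model,
        initial=init,
        stimulus=stimulus,
        t_stop_ms=cfg["experiments"]["threshold_t_stop_ms"],
        dt_ms=cfg["run"]["dt_ms"],
        record_currents=False,
    )
    return extract_features(
        res,
        stim_onset_ms=stimulus.onset_ms,
        settle_ms=stimulus.onset_ms,
    )


def trpm4_sweep(model: CellModel, cfg: Dict[str, Any]) -> SweepResult:
    """TRPM4 conductance sensitivity sweep under the configured
    suprathreshold pulse."""
    e = cfg["experiments"]
    protocol = pulse_template(cfg, amplitude=e["sweep_amplitude"])
    return conductance_sweep(
        model, "trpm4", e["sweep_factors"], protocol,
        t_stop_ms=900.0, dt_ms=cfg["run"]["dt_ms"],
    )


def cat_knockout(model: CellModel, cfg: Dict[str, Any]):
    """T-type Ca2+ knockout with the shipped TRPM4/CaL/KIR compensation
    set, under the just-suprathreshold default pulse."""
    e = cfg["experiments"]
    stim = pulse_template(cfg, amplitude=cfg["stimulus"]["amplitude"])
    return knockout_experiment(
        model,
        e["knockout_mute"],
        e["knockout_compensation"],
        stim,
        t_stop_ms=700.0,
        dt_ms=cfg["run"]["dt_ms"],
    )
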