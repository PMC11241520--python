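"""Deterministic fixture generation.

Writes, under a target directory:

* synthetic steady-state activation curves at known (Ca_half, n) — the
  stand-in for digitized experimental TRPM4 activation points, with the
  generating parameters recorded in the file header;
* short golden voltage traces of the default model under no stimulus,
  the default pulse, and the default alpha synapse;
* a hand-built toy spike trace for feature-extraction tests.

Everything is a plain-text CSV and byte-identical for a given seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Union

import numpy as np

from .config import build_model, build_stimulus, config_hash
from .defaults import default_config
from .fitting import synthetic_activation_curve
from .io import write_trace
from .simulator import SimulationResult, initial_state, run

__all__ = ["make_fixtures", "toy_spike_trace", "ACTIVATION_FIXTURES"]

#: (name, ca_half_mm, hill_n, noise_sd) of the shipped activation fixtures
ACTIVATION_FIXTURES = (
    ("activation_noiseless", 4.0e-4, 2.0, 0.0),
    ("activation_noise02", 4.0e-4, 2.0, 0.02),
    ("activation_steep", 1.0e-3, 4.0, 0.02),
)


def toy_spike_trace(
    rmp_mv: float = -52.0,
    threshold_mv: float = -38.5,
    peak_mv: float = 10.0,
    onset_ms: float = 200.0,
    dt_ms: float = 0.04,
    t_stop_ms: float = 400.0,
) -> SimulationResult:
    """Hand-built trace: rest, linear sub-threshold ramp, fast
    triangular spike, return to rest.  The construction makes the
    threshold crossing (where the slope jumps from 1 mV/ms to
    25 mV/ms) known exactly."""
    t = np.arange(int(round(t_stop_ms / dt_ms)) + 1) * dt_ms
    v = np.full_like(t, rmp_mv)
    ramp_dur = threshold_mv - rmp_mv  # 1 mV/ms ramp
    t_thr = onset_ms + ramp_dur
    up_dur = (peak_mv - threshold_mv) / 25.0
    t_peak = t_thr + up_dur
    down_dur = (peak_mv - (rmp_mv - 8.0)) / 8.0
    t_ahp = t_peak + down_dur
    t_back = t_ahp + 60.0
    seg = (t >= onset_ms) & (t < t_thr)
    v[seg] = rmp_mv + (t[seg] - onset_ms)
    seg = (t >= t_thr) & (t < t_peak)
    v[seg] = threshold_mv + 25.0 * (t[seg] - t_thr)
    seg = (t >= t_peak) & (t < t_ahp)
    v[seg] = peak_mv - 8.0 * (t[seg] - t_peak)
    seg = (t >= t_ahp) & (t < t_back)
    v[seg] = (rmp_mv - 8.0) + 8.0 * (t[seg] - t_ahp) / (t_back - t_ahp)
    v[t >= t_back] = rmp_mv
    cai = np.full_like(t, 1.5e-4)
    return SimulationResult(t_ms=t, v_mv=v, cai_mm=cai, dt_ms=dt_ms)


def make_fixtures(out_dir: Union[str, Path], seed: int = 0) -> List[Path]:
    """Write all fixture files into ``out_dir``; returns the paths.

    Deterministic: the same seed yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    for i, (name, cah, n, sd) in enumerate(ACTIVATION_FIXTURES):
        ds = synthetic_activation_curve(
            ca_half_mm=cah, hill_n=n, noise_sd=sd, seed=seed + i
        )
        path = out / f"{name}.csv"
        lines = [
            f"# ca_half_mm={cah!r} hill_n={n!r} noise_sd={sd!r} seed={seed + i}",
            "cai_mm,activation",
        ]
        for c, a in zip(ds.cai_mm, ds.activation):
            lines.append(f"{c:.17g},{a:.17g}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    cfg = default_config()
    chash = config_hash(cfg)
    model = build_model(cfg)
    init = initial_state(model)
    protocols: Dict[str, object] = {"nostim": None}
    pulse_cfg = default_config()
    protocols["pulse"] = build_stimulus(pulse_cfg)
    alpha_cfg = default_config()
    alpha_cfg["stimulus"]["kind"] = "alpha"
    protocols["alpha"] = build_stimulus(alpha_cfg)
    for name, stim in protocols.items():
        res = run(model, initial=init, stimulus=stim, t_stop_ms=250.0,
                  record_currents=False)
        path = out / f"golden_{name}.csv"
        write_trace(res, path, config_hash=chash,
                    manifest_extra={"protocol": name, "seed": seed})
        written.append(path)

    toy = toy_spike_trace()
    toy_path = out / "toy_spike.csv"
    write_trace(toy, toy_path, manifest_extra={"synthetic": True, "seed": seed})
    written.append(toy_path)
    return written
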