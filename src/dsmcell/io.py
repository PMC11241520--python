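"""Trace serialization and run manifests.

Traces are CSV with units embedded in the header row and full float
precision, so a write/read round trip preserves every sample bitwise.
Each written trace is paired with a JSON run manifest recording the
config hash, package version, step size and output files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .simulator import SimulationResult

__all__ = ["write_trace", "read_trace", "write_manifest"]


def write_trace(
    result: SimulationResult,
    path: Union[str, Path],
    config_hash: Optional[str] = None,
    manifest_extra: Optional[Dict[str, Any]] = None,
) -> Path:
    """Write a trace as CSV (t, v, cai, per-channel current densities)
    plus a paired ``<name>.manifest.json``.

    Floats are written with 17 significant digits (round-trip exact for
    IEEE doubles).
    """
    path = Path(path)
    df = result.as_dataframe()
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise ConfigurationError(f"cannot write trace to {path}: {exc}") from exc
    manifest = {
        "package": "dsmcell",
        "version": __version__,
        "dt_ms": result.dt_ms,
        "t_stop_ms": float(result.t_ms[-1]) if len(result.t_ms) else 0.0,
        "n_samples": int(len(result.t_ms)),
        "config_hash": config_hash,
        "files": [path.name],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = path.with_suffix(path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_trace(path: Union[str, Path]) -> SimulationResult:
    """Read a trace CSV written by :func:`write_trace`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"trace file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_ms", "v_mv", "cai_mm"):
        if col not in df.columns:
            raise ConfigurationError(
                f"trace file {path} lacks required column {col!r}"
            )
    currents = {}
    for col in df.columns:
        if col.startswith("i_") and col.endswith("_ua_cm2"):
            currents[col[2:-7]] = df[col].to_numpy()
    t = df["t_ms"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.04
    return SimulationResult(
        t_ms=t,
        v_mv=df["v_mv"].to_numpy(),
        cai_mm=df["cai_mm"].to_numpy(),
        currents=currents,
        dt_ms=dt,
    )


def write_manifest(path: Union[str, Path], payload: Dict[str, Any]) -> Path:
    """Write a standalone JSON manifest/report."""
    path = Path(path)
    body = dict(payload)
    body.setdefault("package", "dsmcell")
    body.setdefault("version", __version__)
    path.write_text(json.dumps(_jsonable(body), indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
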