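"""Configuration loading, validation and model construction.

Configs are YAML (JSON is valid YAML) documents mirroring the default
schema in :mod:`dsmcell.defaults`.  A loaded document is merged over the
defaults; unknown keys are rejected with an error naming the field and
its expected unit, so silent unit drift cannot happen.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .bk import BKParams
from .calcium import CaPoolParams
from .defaults import UNITS, default_config
from .errors import ConfigurationError
from .gating import GateParams, HHChannelSpec, TauTable
from .geometry import CellGeometry, PassiveProperties, leak_conductance_density
from .simulator import CellModel, Stimulus
from .stimuli import AlphaSynapse, PulseStimulus
from .trpm4 import TRPM4Params

__all__ = [
    "load_config",
    "loads_config",
    "dump_config",
    "config_hash",
    "build_model",
    "build_stimulus",
    "run_settings",
]


def _merge(base: Dict[str, Any], override: Dict[str, Any], path: str) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            unit = UNITS.get(key)
            hint = f" (expected unit: {unit})" if unit else ""
            raise ConfigurationError(f"unknown config key {here!r}{hint}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(
                    f"config key {here!r} must be a mapping"
                )
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _merge_channels(
    base: Dict[str, Any], override: Dict[str, Any]
) -> Dict[str, Any]:
    """Channels are merged per channel; gate blocks are replaced whole
    (a gate given in a user config fully specifies that gate)."""
    out = copy.deepcopy(base)
    for cname, cdict in override.items():
        if cname not in base:
            raise ConfigurationError(
                f"unknown channel {cname!r} in config (known: "
                f"{sorted(base)})"
            )
        if not isinstance(cdict, dict):
            raise ConfigurationError(f"channels.{cname} must be a mapping")
        for key, value in cdict.items():
            here = f"channels.{cname}.{key}"
            if key in ("activation", "inactivation"):
                if value is not None and not isinstance(value, dict):
                    raise ConfigurationError(f"{here} must be a mapping or null")
                out[cname][key] = copy.deepcopy(value)
                continue
            if key not in base[cname] and key not in UNITS:
                raise ConfigurationError(f"unknown config key {here!r}")
            out[cname][key] = copy.deepcopy(value)
    return out


def loads_config(text: str) -> Dict[str, Any]:
    """Parse a YAML/JSON config string and merge it over the defaults."""
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")
    base = default_config()
    channels_override = doc.pop("channels", None)
    merged = _merge(base, doc, "")
    if channels_override is not None:
        if not isinstance(channels_override, dict):
            raise ConfigurationError("channels must be a mapping")
        merged["channels"] = _merge_channels(base["channels"], channels_override)
    _validate(merged)
    return merged


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    """Load a YAML (or JSON) config file, validated and merged over the
    defaults."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    return loads_config(p.read_text())


def dump_config(config: Dict[str, Any], path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config, sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: Dict[str, Any]) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _validate(cfg: Dict[str, Any]) -> None:
    for cname, cdict in cfg["channels"].items():
        g = cdict.get("gmax_s_cm2", 0.0)
        if g is None or g < 0.0:
            raise ConfigurationError(
                f"channels.{cname}.gmax_s_cm2 must be >= 0 "
                f"(unit: {UNITS['gmax_s_cm2']})"
            )
    if cfg["stimulus"]["kind"] not in ("pulse", "alpha", "none"):
        raise ConfigurationError(
            "stimulus.kind must be one of 'pulse', 'alpha', 'none'"
        )
    if cfg["run"]["dt_ms"] <= 0:
        raise ConfigurationError("run.dt_ms must be > 0 ms")


def _gate(block: Optional[Dict[str, Any]], where: str) -> Optional[GateParams]:
    if block is None:
        return None
    allowed = {"v_half_mv", "slope_mv", "tau_ms", "power", "ca_half_mm", "hill_n"}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown gate keys {sorted(unknown)} in {where}"
        )
    tau = block.get("tau_ms", 1.0)
    if isinstance(tau, dict):
        tau = TauTable(tuple(tau["v_mv"]), tuple(tau["tau_ms"]))
    try:
        return GateParams(
            v_half_mv=block.get("v_half_mv"),
            slope_mv=block.get("slope_mv"),
            tau_ms=tau,
            power=int(block.get("power", 1)),
            ca_half_mm=block.get("ca_half_mm"),
            hill_n=block.get("hill_n"),
        )
    except ConfigurationError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def build_model(cfg: Dict[str, Any]) -> CellModel:
    """Assemble a :class:`CellModel` from a validated config dict.

    The ohmic leak channel is derived from the passive properties
    (conductance = 1/Rm, reversal = passive.e_leak_mv) and appended to
    the HH channel bank.
    """
    geom = CellGeometry(**cfg["geometry"])
    passive = PassiveProperties(**cfg["passive"])
    chans = []
    for cname, cdict in cfg["channels"].items():
        if cname in ("bk", "trpm4"):
            continue
        chans.append(
            HHChannelSpec(
                name=cname,
                gmax_s_cm2=cdict["gmax_s_cm2"],
                e_rev_mv=cdict["e_rev_mv"],
                activation=_gate(cdict.get("activation"), f"channels.{cname}.activation"),
                inactivation=_gate(
                    cdict.get("inactivation"), f"channels.{cname}.inactivation"
                ),
                is_calcium=bool(cdict.get("is_calcium", False)),
                open_fraction=float(cdict.get("open_fraction", 1.0)),
            )
        )
    chans.append(
        HHChannelSpec(
            name="leak",
            gmax_s_cm2=leak_conductance_density(passive),
            e_rev_mv=passive.e_leak_mv,
        )
    )
    bk_cfg = dict(cfg["channels"]["bk"])
    bk = BKParams(
        gmax_s_cm2=bk_cfg["gmax_s_cm2"],
        e_k_mv=bk_cfg["e_k_mv"],
        k_on=bk_cfg["k_on"],
        k_coff=bk_cfg["k_coff"],
        k_ooff=bk_cfg["k_ooff"],
        co_rates=tuple(bk_cfg["co_rates"]),
        oc_rates=tuple(bk_cfg["oc_rates"]),
        a_efold_mv=bk_cfg["a_efold_mv"],
        b_efold_mv=bk_cfg["b_efold_mv"],
        conducting_states=tuple(bk_cfg["conducting_states"]),
    )
    tp_cfg = cfg["channels"]["trpm4"]
    trpm4 = TRPM4Params(
        gmax_s_cm2=tp_cfg["gmax_s_cm2"],
        e_rev_mv=tp_cfg["e_rev_mv"],
        ca_half_mm=tp_cfg["ca_half_mm"],
        hill_n=tp_cfg["hill_n"],
        tau_m_ms=tp_cfg["tau_m_ms"],
        power=int(tp_cfg["power"]),
    )
    ca = CaPoolParams(**cfg["calcium"])
    return CellModel(
        geometry=geom,
        passive=passive,
        hh_channels=tuple(chans),
        bk=bk,
        trpm4=trpm4,
        ca_pool=ca,
    )


def build_stimulus(cfg: Dict[str, Any]) -> Stimulus:
    """Build the stimulus described by the ``stimulus:`` block (or None
    for kind 'none')."""
    s = cfg["stimulus"]
    if s["kind"] == "none":
        return None
    if s["kind"] == "pulse":
        return PulseStimulus(
            amplitude=s["amplitude"],
            onset_ms=s["onset_ms"],
            duration_ms=s["duration_ms"],
            unit_na=s["unit_na"],
        )
    return AlphaSynapse(
        g_peak_us=s["g_peak_us"],
        tau_alpha_ms=s["tau_alpha_ms"],
        e_syn_mv=s["e_syn_mv"],
        onset_ms=s["onset_ms"],
    )


def run_settings(cfg: Dict[str, Any]) -> Dict[str, Any]:
    """The ``run:`` block (dt, t_stop, settle window, initialization)."""
    return dict(cfg["run"])
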