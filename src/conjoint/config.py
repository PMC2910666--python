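"""Configuration handling: JSON dialect, defaults, validation, overrides.

A run is described by a nested JSON document (the single supported config
dialect).  Every field is optional; unspecified fields fall back to the
coupled untreated baseline scenario.  Unknown keys are rejected with the
offending key named, and a resolved config round-trips through write/read
bit-exactly.

Top-level keys::

    normal   {rate, capacity, shape}          intrinsic normal-cell growth
    tumor    {rate, capacity, shape}          intrinsic tumor growth
    interaction {variant, beta, k, t_crit, rho0, rho1, k_scale, hill_m}
    drug     {mode, u0, d, m, a_N, a_T, t_rx, lumped_kill_N, lumped_kill_T}
    N0, T0                                    initial sizes (cells)
    t_end, dt                                 horizon and sample step (time)
    therapy_trigger                           "fixed_time" | "tumor_exceeds_tcrit"
    output   {timeseries, summary, plot}      optional file paths
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

from .engine import ModelSpec
from .errors import ConfigError
from .growth import GrowthLaw
from .interactions import InteractionParams
from .pharmacology import DrugProgram

__all__ = [
    "RunConfig",
    "default_config",
    "resolve_config",
    "config_to_spec",
    "spec_to_config",
    "read_config",
    "write_config",
    "apply_overrides",
]

# Coupled untreated baseline (the registry's fig1_right scenario).
_DEFAULTS: Dict[str, Any] = {
    "normal": {"rate": 0.4, "capacity": 1e6, "shape": 1.0},
    "tumor": {"rate": 0.3, "capacity": 1.2e6, "shape": 1.0},
    "interaction": {
        "variant": "default",
        "beta": 2.0,
        "k": 1.0,
        "t_crit": 3e5,
        "rho0": 1.0,
        "rho1": 1000.0,
        "k_scale": None,
        "hill_m": None,
    },
    "drug": {
        "mode": "none",
        "u0": 0.0,
        "d": 0.0,
        "m": 1.0,
        "a_N": 0.0,
        "a_T": 0.0,
        "t_rx": 40.0,
        "lumped_kill_N": None,
        "lumped_kill_T": None,
    },
    "N0": 1.0,
    "T0": 1.0,
    "t_end": 100.0,
    "dt": 0.1,
    "therapy_trigger": "fixed_time",
    "output": {"timeseries": None, "summary": None, "plot": None},
}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run configuration and its assembled model."""

    resolved: Dict[str, Any]
    spec: ModelSpec

    def to_dict(self) -> Dict[str, Any]:
        return copy.deepcopy(self.resolved)


def default_config() -> Dict[str, Any]:
    """A deep copy of the fully defaulted baseline configuration."""
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults: Dict[str, Any], user: Dict[str, Any], prefix: str = "") -> Dict[str, Any]:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        path = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {path!r} must be a mapping")
            out[key] = _merge(defaults[key], val, prefix=f"{path}.")
        else:
            out[key] = val
    return out


def resolve_config(partial: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Merge a partial config onto the defaults, rejecting unknown keys."""
    merged = _merge(_DEFAULTS, partial or {})
    # Assemble once so every invariant is checked with the offending key context
    config_to_spec(merged)
    return merged


def config_to_spec(cfg: Dict[str, Any]) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from a resolved config dict."""
    try:
        hill_m = cfg["interaction"]["hill_m"]
        return ModelSpec(
            normal_law=GrowthLaw(**cfg["normal"]),
            tumor_law=GrowthLaw(**cfg["tumor"]),
            interaction=InteractionParams(
                variant=cfg["interaction"]["variant"],
                beta=cfg["interaction"]["beta"],
                k=cfg["interaction"]["k"],
                t_crit=cfg["interaction"]["t_crit"],
                rho0=cfg["interaction"]["rho0"],
                rho1=cfg["interaction"]["rho1"],
                k_scale=cfg["interaction"]["k_scale"],
                hill_m=None if hill_m is None else int(hill_m),
            ),
            drug=DrugProgram(**cfg["drug"]),
            N0=cfg["N0"],
            T0=cfg["T0"],
            t_end=cfg["t_end"],
            dt=cfg["dt"],
            therapy_trigger=cfg["therapy_trigger"],
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed config: {exc}") from exc


def spec_to_config(spec: ModelSpec) -> Dict[str, Any]:
    """Serialize a :class:`ModelSpec` back into the config dialect."""
    cfg = default_config()
    cfg["normal"] = {
        "rate": spec.normal_law.rate,
        "capacity": spec.normal_law.capacity,
        "shape": spec.normal_law.shape,
    }
    cfg["tumor"] = {
        "rate": spec.tumor_law.rate,
        "capacity": spec.tumor_law.capacity,
        "shape": spec.tumor_law.shape,
    }
    p = spec.interaction
    cfg["interaction"] = {
        "variant": p.variant,
        "beta": p.beta,
        "k": p.k,
        "t_crit": p.t_crit,
        "rho0": p.rho0,
        "rho1": p.rho1,
        "k_scale": p.k_scale,
        "hill_m": p.hill_m,
    }
    d = spec.drug
    cfg["drug"] = {
        "mode": d.mode,
        "u0": d.u0,
        "d": d.d,
        "m": d.m,
        "a_N": d.a_N,
        "a_T": d.a_T,
        "t_rx": d.t_rx,
        "lumped_kill_N": d.lumped_kill_N,
        "lumped_kill_T": d.lumped_kill_T,
    }
    cfg["N0"] = spec.N0
    cfg["T0"] = spec.T0
    cfg["t_end"] = spec.t_end
    cfg["dt"] = spec.dt
    cfg["therapy_trigger"] = spec.therapy_trigger
    return cfg


def read_config(path) -> RunConfig:
    """Read, validate and fully resolve a JSON config file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a JSON object, got {type(data).__name__}")
    resolved = resolve_config(data)
    return RunConfig(resolved=resolved, spec=config_to_spec(resolved))


def write_config(cfg: Dict[str, Any], path) -> None:
    """Write a config dict as formatted JSON (read_config inverts this)."""
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")


def _parse_override_value(raw: str) -> Any:
    try:
        return json.loads(raw)
    except json.JSONDecodeError:
        return raw


def apply_overrides(cfg: Dict[str, Any], overrides: Dict[str, Any]) -> Dict[str, Any]:
    """Apply dotted-key overrides (e.g. ``{"drug.u0": 3}``) onto a config.

    String values are parsed as JSON scalars where possible, so CLI
    ``--param drug.u0=3`` arrives as the number 3.
    """
    out = copy.deepcopy(cfg)
    for dotted, value in overrides.items():
        if isinstance(value, str):
            value = _parse_override_value(value)
        parts = dotted.split(".")
        node = out
        for part in parts[:-1]:
            if not isinstance(node.get(part), dict):
                raise ConfigError(f"unknown config key: {dotted!r}")
            node = node[part]
        leaf = parts[-1]
        if leaf not in node or isinstance(node[leaf], dict):
            raise ConfigError(f"unknown config key: {dotted!r}")
        node[leaf] = value
    return resolve_config(out)
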