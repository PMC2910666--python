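"""Named scenario presets and the scenario runner.

Each preset is a fully resolved configuration for one regime studied with
the conjoint model:

* ``fig1_left`` / ``fig1_right`` — decoupled vs coupled growth, untreated.
* ``fig2_row*`` — static drug: tumor-only kill, both-compartment kill with
  tumor emphasis, both-compartment kill with normal emphasis.
* ``fig3_row*`` — exponentially decaying drug at two initial amounts and
  four decay rates.
* ``fig4_*`` — Gompertzian tumor growth (therapy triggered when the tumor
  reaches the critical size), untreated and at two static kill strengths.

The Gompertz presets exist in two flavours.  The literal ones use the
plateau ``h = 1e5``; because that plateau lies below the critical size
``T* = 3e5``, the tumor never reaches ``T*`` and size-triggered therapy
never engages — the parameter set is internally inconsistent with the
regime it is meant to produce.  The ``fig4_consistent_*`` presets keep
every other parameter but raise the plateau to ``1.2e6`` (matching the
logistic tumor's carrying capacity, which the Gompertz tumor is described
as approaching), restoring the crossing and the therapy trigger.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Any, Dict, Optional, Tuple, Union

from .config import (
    apply_overrides,
    config_to_spec,
    default_config,
    resolve_config,
    spec_to_config,
)
from .engine import (
    ModelSpec,
    Trajectory,
    first_crossing_time,
    inhibition_onset_delay,
    peak,
    simulate,
)
from .errors import ConfigError, EngineError

__all__ = ["PRESETS", "get_preset", "preset_config", "run_scenario", "ScenarioResult"]


def _model1(**edits) -> Dict[str, Any]:
    cfg = default_config()
    for dotted, value in edits.items():
        node = cfg
        parts = dotted.split("__")
        for part in parts[:-1]:
            node = node[part]
        node[parts[-1]] = value
    return cfg


def _static(kill_N: float, kill_T: float) -> Dict[str, Any]:
    return _model1(
        drug__mode="static",
        drug__lumped_kill_N=kill_N,
        drug__lumped_kill_T=kill_T,
    )


def _decay(u0: float, d: float) -> Dict[str, Any]:
    return _model1(
        drug__mode="exp_decay",
        drug__u0=u0,
        drug__d=d,
        drug__a_N=0.0,
        drug__a_T=0.1,
    )


def _gompertz(capacity: float, kill_T: Optional[float]) -> Dict[str, Any]:
    cfg = _model1(
        tumor__rate=0.083,
        tumor__capacity=capacity,
        tumor__shape=0.0,
        t_end=60.0,
    )
    if kill_T is not None:
        cfg["drug"]["mode"] = "static"
        cfg["drug"]["lumped_kill_N"] = 0.0
        cfg["drug"]["lumped_kill_T"] = kill_T
        cfg["therapy_trigger"] = "tumor_exceeds_tcrit"
    return cfg


_H_LITERAL = 1e5
_H_CONSISTENT = 1.2e6

_REGISTRY: Dict[str, Dict[str, Any]] = {
    "fig1_left": _model1(interaction__beta=0.0, interaction__k=0.0),
    "fig1_right": _model1(),
    # static drug, tumor-only kill
    "fig2_row1_red": _static(0.0, 0.01),
    "fig2_row1_green": _static(0.0, 0.05),
    "fig2_row1_black": _static(0.0, 0.1),
    # static drug, tumor kill fixed at 0.1, normal kill varied
    "fig2_row2_red": _static(0.01, 0.1),
    "fig2_row2_green": _static(0.05, 0.1),
    "fig2_row2_black": _static(0.1, 0.1),
    # static drug, normal kill fixed at 0.1, tumor kill varied
    "fig2_row3_red": _static(0.1, 0.01),
    "fig2_row3_green": _static(0.1, 0.05),
    "fig2_row3_black": _static(0.1, 0.1),
    # exponentially decaying drug, u0 = 1
    "fig3_row1_red": _decay(1.0, 0.1),
    "fig3_row1_green": _decay(1.0, 0.5),
    "fig3_row1_black": _decay(1.0, 1.0),
    "fig3_row1_brown": _decay(1.0, 2.0),
    # exponentially decaying drug, u0 = 3
    "fig3_row2_red": _decay(3.0, 0.1),
    "fig3_row2_green": _decay(3.0, 0.5),
    "fig3_row2_black": _decay(3.0, 1.0),
    "fig3_row2_brown": _decay(3.0, 2.0),
    # Gompertzian tumor, literal printed plateau h = 1e5
    "fig4_untreated": _gompertz(_H_LITERAL, None),
    "fig4_treated_weak": _gompertz(_H_LITERAL, 0.1),
    "fig4_treated_strong": _gompertz(_H_LITERAL, 0.17),
    # Gompertzian tumor, plateau matched to the logistic carrying capacity
    "fig4_consistent_untreated": _gompertz(_H_CONSISTENT, None),
    "fig4_consistent_treated_weak": _gompertz(_H_CONSISTENT, 0.1),
    "fig4_consistent_treated_strong": _gompertz(_H_CONSISTENT, 0.17),
}

PRESETS = tuple(sorted(_REGISTRY))


def preset_config(name: str) -> Dict[str, Any]:
    """Resolved config dict of a named preset."""
    if name not in _REGISTRY:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        )
    return copy.deepcopy(_REGISTRY[name])


def get_preset(name: str) -> ModelSpec:
    """Fully resolved :class:`ModelSpec` of a named preset."""
    return config_to_spec(preset_config(name))


@dataclass
class ScenarioResult:
    """Trajectory plus the derived scenario metrics.

    ``inhibition_delay`` compares the normal-cell peak time against the
    matching untreated twin (same parameters, drug off); it is ``None`` for
    untreated scenarios and ``inf`` when the treated normal population is
    still rising at the end of the horizon.
    """

    name: Optional[str]
    spec: ModelSpec
    trajectory: Trajectory
    tcrit_crossing: Optional[float]
    normal_peak: Tuple[float, float]
    terminal: Tuple[float, float]
    inhibition_delay: Optional[float]
    config: Dict[str, Any]


def run_scenario(
    scenario: Union[str, ModelSpec],
    overrides: Optional[Dict[str, Any]] = None,
) -> ScenarioResult:
    """Integrate a preset or explicit spec and compute all derived metrics.

    Fully deterministic: the same scenario and overrides always produce the
    same result.
    """
    if isinstance(scenario, str):
        name: Optional[str] = scenario
        cfg = preset_config(scenario)
    else:
        name = None
        cfg = resolve_config(spec_to_config(scenario))
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    spec = config_to_spec(cfg)

    try:
        traj = simulate(spec)
    except EngineError as exc:
        raise EngineError(
            f"scenario {name or '<custom>'}: {exc}", t=exc.t, state=exc.state
        ) from exc

    tcrit = first_crossing_time(traj, "T", spec.interaction.t_crit)
    npeak = peak(traj, "N")
    terminal = (float(traj.N[-1]), float(traj.T[-1]))

    delay: Optional[float] = None
    if spec.drug.mode != "none":
        twin_cfg = copy.deepcopy(cfg)
        twin_cfg["drug"] = default_config()["drug"]
        untreated = simulate(config_to_spec(twin_cfg))
        delay = inhibition_onset_delay(traj, untreated, t_crit=spec.interaction.t_crit)
        if math.isinf(delay):
            delay = math.inf

    return ScenarioResult(
        name=name,
        spec=spec,
        trajectory=traj,
        tcrit_crossing=tcrit,
        normal_peak=npeak,
        terminal=terminal,
        inhibition_delay=delay,
        config=cfg,
    )
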