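"""Serialization of trajectories and scenario summaries, plus plotting.

Time series are written as RFC-4180 CSV (``.`` decimal separator) with the
header ``t,N,T,u,kill_N,kill_T``; floats use Python's shortest round-trip
representation, so re-reading the file reproduces the sampled trajectory
exactly and the byte output is deterministic for a fixed trajectory.

Summaries are versioned JSON documents holding the derived metrics and the
fully resolved configuration; :func:`validate_summary` checks a document
against the shipped schema.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Any, Dict

import numpy as np

from .engine import Trajectory
from .errors import ConfigError
from .scenarios import ScenarioResult

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_summary",
    "validate_summary",
    "plot_trajectory",
    "SUMMARY_SCHEMA",
]

TIMESERIES_COLUMNS = ("t", "N", "T", "u", "kill_N", "kill_T")

# field -> (type, nullable)
SUMMARY_SCHEMA: Dict[str, Any] = {
    "schema_version": (int, False),
    "preset": (str, True),
    "metrics": {
        "tcrit_crossing": (float, True),
        "normal_peak_time": (float, False),
        "normal_peak_value": (float, False),
        "terminal_N": (float, False),
        "terminal_T": (float, False),
        "inhibition_delay": (float, True),
        "inhibition_delay_censored": (bool, False),
    },
    "config": (dict, False),
}


def write_timeseries(traj: Trajectory, path) -> None:
    """Write the sampled trajectory as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TIMESERIES_COLUMNS)
        for row in zip(traj.times, traj.N, traj.T, traj.u, traj.kill_N, traj.kill_T):
            writer.writerow([repr(float(v)) for v in row])


def read_timeseries(path) -> Trajectory:
    """Read a trajectory CSV back (no dense output on the round trip)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = tuple(next(reader))
        if header != TIMESERIES_COLUMNS:
            raise ConfigError(f"unexpected CSV header {header}")
        rows = [[float(v) for v in row] for row in reader]
    arr = np.asarray(rows, dtype=float)
    return Trajectory(
        times=arr[:, 0],
        N=arr[:, 1],
        T=arr[:, 2],
        u=arr[:, 3],
        kill_N=arr[:, 4],
        kill_T=arr[:, 5],
        segments=[],
    )


def summary_document(result: ScenarioResult) -> Dict[str, Any]:
    """Build the versioned summary dict for a scenario result."""
    delay = result.inhibition_delay
    censored = delay is not None and math.isinf(delay)
    return {
        "schema_version": 1,
        "preset": result.name,
        "metrics": {
            "tcrit_crossing": result.tcrit_crossing,
            "normal_peak_time": result.normal_peak[0],
            "normal_peak_value": result.normal_peak[1],
            "terminal_N": result.terminal[0],
            "terminal_T": result.terminal[1],
            "inhibition_delay": None if censored else delay,
            "inhibition_delay_censored": censored,
        },
        "config": result.config,
    }


def write_summary(result: ScenarioResult, path) -> Dict[str, Any]:
    """Write the scenario summary as JSON; returns the document."""
    doc = summary_document(result)
    validate_summary(doc)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def _check(value, spec, where: str) -> None:
    if isinstance(spec, dict):
        if not isinstance(value, dict):
            raise ConfigError(f"summary field {where!r} must be an object")
        for key, sub in spec.items():
            if key not in value:
                raise ConfigError(f"summary field {where}.{key} missing")
            _check(value[key], sub, f"{where}.{key}")
        return
    typ, nullable = spec
    if value is None:
        if not nullable:
            raise ConfigError(f"summary field {where!r} may not be null")
        return
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        return
    if not isinstance(value, typ) or (typ is not bool and isinstance(value, bool)):
        raise ConfigError(
            f"summary field {where!r} must be {typ.__name__}, got {type(value).__name__}"
        )


def validate_summary(doc: Dict[str, Any]) -> None:
    """Check a summary document against :data:`SUMMARY_SCHEMA`."""
    if not isinstance(doc, dict):
        raise ConfigError("summary must be an object")
    for key, spec in SUMMARY_SCHEMA.items():
        if key not in doc:
            raise ConfigError(f"summary field {key!r} missing")
        _check(doc[key], spec, key)


def plot_trajectory(traj: Trajectory, path, title: str | None = None) -> None:
    """Two stacked panels: population sizes and drug level over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_pop, ax_drug) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 6), height_ratios=[3, 1]
    )
    ax_pop.plot(traj.times, traj.N, label="normal cells N", color="tab:blue")
    ax_pop.plot(traj.times, traj.T, label="tumor cells T", color="tab:purple")
    ax_pop.set_ylabel("population (cells)")
    ax_pop.legend(loc="best")
    if title:
        ax_pop.set_title(title)
    ax_drug.plot(traj.times, traj.u, color="tab:red")
    ax_drug.set_ylabel("drug u(t)")
    ax_drug.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
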