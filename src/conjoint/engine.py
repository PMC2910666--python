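"""Assembly and integration of the coupled normal-tumor system.

The right-hand side sums, per compartment, the intrinsic growth flux, the
coupling flux and the drug kill term:

    dN/dt = g_N(N) + f_N(T)*N - F_N(u(t))*N
    dT/dt = g_T(T) + f_T(N,T) - F_T(u(t))*T

Integration is adaptive (LSODA, rtol 1e-10 / atol 1e-8) and piecewise across
the therapy-start discontinuity so the step change in the right-hand side
falls on a breakpoint.  Trajectories carry dense output for refining event
times (threshold crossings, population peaks) far below the sampling step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .errors import DomainError, EngineError
from .growth import GrowthLaw, generalized_growth_flux
from .interactions import InteractionParams, normal_coupling_flux, tumor_modifier
from .pharmacology import DrugProgram

__all__ = [
    "ModelSpec",
    "Trajectory",
    "rhs",
    "simulate",
    "first_crossing_time",
    "peak",
    "inhibition_onset_delay",
    "trajectory_distance",
]

RTOL = 1e-10
ATOL = 1e-8
_ZERO_FLOOR = 1e-9  # values this close to 0 are reported as extinct

TRIGGERS = ("fixed_time", "tumor_exceeds_tcrit")


@dataclass(frozen=True)
class ModelSpec:
    """Complete, integrable description of one simulation.

    ``therapy_trigger`` selects how the therapy start is determined:
    ``"fixed_time"`` uses ``drug.t_rx`` directly, while
    ``"tumor_exceeds_tcrit"`` starts the drug at the first time the tumor
    reaches the critical size ``interaction.t_crit`` (the moment the normal
    cells enter their inhibition phase).
    """

    normal_law: GrowthLaw
    tumor_law: GrowthLaw
    interaction: InteractionParams = field(default_factory=InteractionParams)
    drug: DrugProgram = field(default_factory=DrugProgram)
    N0: float = 1.0
    T0: float = 1.0
    t_end: float = 100.0
    dt: float = 0.1
    therapy_trigger: str = "fixed_time"

    def __post_init__(self) -> None:
        if self.N0 < 0 or self.T0 < 0:
            raise DomainError("initial populations must be non-negative")
        if not (self.t_end > 0):
            raise DomainError(f"t_end must be > 0, got {self.t_end}")
        if not (0 < self.dt <= self.t_end):
            raise DomainError(f"dt must be in (0, t_end], got {self.dt}")
        if self.therapy_trigger not in TRIGGERS:
            raise DomainError(
                f"unknown therapy_trigger {self.therapy_trigger!r}; "
                f"choose from {TRIGGERS}"
            )

    def resolved_interaction(self) -> InteractionParams:
        """Interaction parameters with ``k_scale`` defaulted to K_T."""
        p = self.interaction
        if p.k_scale is None:
            p = replace(p, k_scale=self.tumor_law.capacity)
        return p


@dataclass
class Trajectory:
    """Sampled (t, N, T, u) path with dense-output access.

    ``dense(t)`` evaluates the underlying adaptive solution anywhere on
    ``[times[0], times[-1]]`` (clipped at 0 from below), which event
    refinement uses to locate crossings and peaks to ~1e-6 time units.
    """

    times: np.ndarray
    N: np.ndarray
    T: np.ndarray
    u: np.ndarray
    kill_N: np.ndarray
    kill_T: np.ndarray
    segments: List[Tuple[float, float, object]] = field(default_factory=list)

    def dense(self, t: float) -> Tuple[float, float]:
        """(N, T) at arbitrary time ``t`` within the integrated horizon.

        Trajectories without stored solver output (e.g. read back from CSV)
        fall back to linear interpolation on the sample grid.
        """
        if not self.segments:
            lo, hi = float(self.times[0]), float(self.times[-1])
            if not (lo <= t <= hi):
                raise DomainError(f"t={t} outside sampled horizon [{lo}, {hi}]")
            return (
                max(float(np.interp(t, self.times, self.N)), 0.0),
                max(float(np.interp(t, self.times, self.T)), 0.0),
            )
        lo = self.segments[0][0]
        hi = self.segments[-1][1]
        if not (lo <= t <= hi):
            raise DomainError(f"t={t} outside integrated horizon [{lo}, {hi}]")
        for t0, t1, sol in self.segments:
            if t <= t1 or (t0, t1, sol) is self.segments[-1]:
                y = sol(t)
                return max(float(y[0]), 0.0), max(float(y[1]), 0.0)
        raise AssertionError("unreachable")

    def component(self, which: str) -> np.ndarray:
        if which not in ("N", "T"):
            raise DomainError(f"compartment must be 'N' or 'T', got {which!r}")
        return self.N if which == "N" else self.T


def rhs(t: float, N: float, T: float, spec: ModelSpec) -> Tuple[float, float]:
    """Model right-hand side (dN/dt, dT/dt) at state (N, T), cells/time.

    With the interaction and drug switched off this reduces exactly to the
    two decoupled intrinsic growth laws.
    """
    if not (math.isfinite(N) and math.isfinite(T)):
        raise EngineError(f"non-finite state at t={t}: N={N}, T={T}", t=t, state=(N, T))
    if N < 0 or T < 0:
        raise DomainError(f"negative state at t={t}: N={N}, T={T}")
    p = spec.resolved_interaction()
    kN, kT = spec.drug.percapita_kill(t)
    dN = generalized_growth_flux(N, spec.normal_law) + normal_coupling_flux(N, T, p) - kN * N
    dT = generalized_growth_flux(T, spec.tumor_law) + tumor_modifier(N, T, p) - kT * T
    return dN, dT


def _resolve_therapy_start(spec: ModelSpec) -> Optional[float]:
    """Effective therapy start time, or None if the drug never engages."""
    if spec.drug.mode == "none":
        return None
    if spec.therapy_trigger == "fixed_time":
        return spec.drug.t_rx if spec.drug.t_rx < spec.t_end else None
    # tumor_exceeds_tcrit: integrate drug-free until T reaches T*
    untreated = replace(spec, drug=DrugProgram(mode="none"), therapy_trigger="fixed_time")
    tc = spec.resolved_interaction().t_crit
    if spec.T0 >= tc:
        return 0.0

    def event(t, y):
        return y[1] - tc

    event.terminal = True
    event.direction = 1
    sol = solve_ivp(
        lambda t, y: _clamped_rhs(t, y, untreated),
        (0.0, spec.t_end),
        [spec.N0, spec.T0],
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        events=event,
    )
    if sol.status == -1:
        raise EngineError(sol.message, t=sol.t[-1], state=tuple(sol.y[:, -1]))
    if sol.t_events[0].size == 0:
        return None
    return float(sol.t_events[0][0])


def _clamped_rhs(t, y, spec: ModelSpec):
    # The integrator may probe marginally negative states; clamp before
    # evaluating so extinction stays absorbing.
    dN, dT = rhs(t, max(y[0], 0.0), max(y[1], 0.0), spec)
    return [dN, dT]


def simulate(spec: ModelSpec) -> Trajectory:
    """Integrate the coupled system over ``[0, t_end]``.

    Piecewise across the (resolved) therapy start so the drug-onset
    discontinuity is a breakpoint; sampled on a uniform grid of step
    ``spec.dt`` with dense output retained for event refinement.
    """
    t_rx = _resolve_therapy_start(spec)
    drug = spec.drug if t_rx is None else spec.drug.with_start(t_rx)
    if t_rx is None and spec.drug.mode != "none":
        # therapy never engages within the horizon
        drug = DrugProgram(mode="none")
    eff = replace(spec, drug=drug, therapy_trigger="fixed_time")

    breaks = [0.0]
    if t_rx is not None and 0.0 < t_rx < spec.t_end:
        breaks.append(t_rx)
    breaks.append(spec.t_end)

    segments: List[Tuple[float, float, object]] = []
    y = [float(spec.N0), float(spec.T0)]
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        sol = solve_ivp(
            lambda t, yy: _clamped_rhs(t, yy, eff),
            (t0, t1),
            y,
            method="LSODA",
            rtol=RTOL,
            atol=ATOL,
            dense_output=True,
        )
        if sol.status == -1:
            raise EngineError(sol.message, t=float(sol.t[-1]), state=tuple(sol.y[:, -1]))
        segments.append((t0, t1, sol.sol))
        y = [float(sol.y[0, -1]), float(sol.y[1, -1])]

    n_steps = int(round(spec.t_end / spec.dt))
    times = np.linspace(0.0, spec.t_end, n_steps + 1)
    N_path = np.empty_like(times)
    T_path = np.empty_like(times)
    seg_idx = 0
    for i, t in enumerate(times):
        while seg_idx < len(segments) - 1 and t > segments[seg_idx][1]:
            seg_idx += 1
        yv = segments[seg_idx][2](t)
        N_path[i], T_path[i] = yv[0], yv[1]
    N_path = np.where(np.abs(N_path) < _ZERO_FLOOR, 0.0, np.clip(N_path, 0.0, None))
    T_path = np.where(np.abs(T_path) < _ZERO_FLOOR, 0.0, np.clip(T_path, 0.0, None))
    N_path[0], T_path[0] = spec.N0, spec.T0

    from .pharmacology import drug_level  # local to avoid cycle at import time

    u_path = np.array([drug_level(t, drug) for t in times])
    kills = np.array([drug.percapita_kill(t) for t in times])
    return Trajectory(
        times=times,
        N=N_path,
        T=T_path,
        u=u_path,
        kill_N=kills[:, 0],
        kill_T=kills[:, 1],
        segments=segments,
    )


def first_crossing_time(
    traj: Trajectory, which: str, threshold: float
) -> Optional[float]:
    """Earliest time the compartment reaches ``threshold``, or None.

    The grid bracket is refined on dense output to |dt| <= 1e-6; a
    trajectory already at or above the threshold at its first sample
    reports that first time.
    """
    if not (threshold > 0):
        raise DomainError(f"threshold must be > 0, got {threshold}")
    vals = traj.component(which)
    above = vals >= threshold
    if above[0]:
        return float(traj.times[0])
    idx = np.argmax(above)
    if not above[idx]:
        return None
    t0, t1 = float(traj.times[idx - 1]), float(traj.times[idx])
    comp = 0 if which == "N" else 1

    def g(t):
        return traj.dense(t)[comp] - threshold

    g0, g1 = g(t0), g(t1)
    if g0 >= 0:
        return t0
    if g1 < 0:  # dense output disagrees with grid rounding; keep grid time
        return t1
    return float(brentq(g, t0, t1, xtol=1e-6))


def peak(traj: Trajectory, which: str) -> Tuple[float, float]:
    """Time and value of the first global maximum of a compartment.

    Ties break toward the earliest time; the grid maximum is refined on
    dense output within its neighbouring interval.
    """
    vals = traj.component(which)
    if vals.size == 0:
        raise DomainError("empty trajectory")
    i = int(np.argmax(vals))
    comp = 0 if which == "N" else 1
    lo = float(traj.times[max(i - 1, 0)])
    hi = float(traj.times[min(i + 1, vals.size - 1)])
    best_t, best_v = float(traj.times[i]), float(vals[i])
    if hi > lo:
        res = minimize_scalar(
            lambda t: -traj.dense(t)[comp],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        cand_t, cand_v = float(res.x), float(-res.fun)
        if cand_v > best_v or (cand_v == best_v and cand_t < best_t):
            best_t, best_v = cand_t, cand_v
    return best_t, best_v


def inhibition_onset_delay(
    treated: Trajectory,
    untreated: Trajectory,
    t_crit: Optional[float] = None,
) -> float:
    """Delay of the treated normal-cell peak relative to the untreated one.

    Positive when therapy postpones the inhibition phase.  The onset is
    censored — reported as ``inf`` — when the treated normal population is
    still rising at the end of the horizon, or when ``t_crit`` is given and
    the treated tumor never reaches it (the GMF inhibition regime is never
    entered, so there is no onset to date).
    """
    if not np.array_equal(treated.times, untreated.times):
        raise DomainError("trajectories must share the same sample grid")
    if t_crit is not None and float(np.max(treated.T)) < t_crit:
        return math.inf
    i_treated = int(np.argmax(treated.N))
    if i_treated == treated.N.size - 1:
        return math.inf
    t_treated, _ = peak(treated, "N")
    t_untreated, _ = peak(untreated, "N")
    return t_treated - t_untreated


def trajectory_distance(a: Trajectory, b: Trajectory) -> float:
    """Scale-free L2 distance between two trajectories on a shared grid.

    The stacked (N, T) difference norm divided by the larger of the two
    stacked path norms: symmetric, 0 iff the sampled paths are identical.
    """
    if not np.array_equal(a.times, b.times):
        raise DomainError("trajectories must share the same sample grid")
    xa = np.concatenate([a.N, a.T])
    xb = np.concatenate([b.N, b.T])
    denom = max(np.linalg.norm(xa), np.linalg.norm(xb))
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(xa - xb) / denom)
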