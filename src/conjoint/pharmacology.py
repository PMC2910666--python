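"""Drug exposure schedules and the pharmacodynamic cell-kill response.

The per-capita kill rate of compartment ``i`` follows the fractional-cell-kill
law ``F(u) = a_i * (1 - exp(-m*u))``: zero without drug, saturating at the
response coefficient ``a_i`` for large drug amount ``u``.  The exposure
``u(t)`` is either absent, static (constant ``u0``), or exponentially decaying
``u0 * exp(-d * (t - t_rx))`` with the decay clock referenced to the therapy
start ``t_rx`` (``u0`` is the amount administered, so it applies at
administration time).  No drug is present before ``t_rx``.

Static schedules may alternatively be specified by the lumped per-capita kill
constant ``a_i * (1 - exp(-m*u0))`` directly (``lumped_kill_N/T``); both entry
styles produce bit-identical dynamics because the constant is resolved once.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import ConfigError, DomainError

__all__ = ["DrugProgram", "drug_level", "kill_rate", "MODES"]

MODES = ("none", "static", "exp_decay")


@dataclass(frozen=True)
class DrugProgram:
    """A chemotherapy exposure schedule plus the cellular response.

    Attributes
    ----------
    mode : str
        ``"none"`` (untreated), ``"static"`` (constant level) or
        ``"exp_decay"`` (level decays exponentially after therapy start).
    u0 : float
        Initial / constant drug amount (dimensionless concentration units).
    d : float
        Exponential decay rate, 1/time (exp_decay mode).
    m : float
        Pharmacokinetic exponent of the fractional-kill law (default 1).
    a_N, a_T : float
        Response coefficients (saturating kill-rate ceilings), 1/time.
    t_rx : float
        Therapy start time.
    lumped_kill_N, lumped_kill_T : float, optional
        Static-mode shorthand: the constant per-capita kill
        ``a_i*(1-exp(-m*u0))`` entered as a single number.
    """

    mode: str = "none"
    u0: float = 0.0
    d: float = 0.0
    m: float = 1.0
    a_N: float = 0.0
    a_T: float = 0.0
    t_rx: float = 40.0
    lumped_kill_N: Optional[float] = None
    lumped_kill_T: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown drug mode {self.mode!r}; choose from {MODES}")
        if self.u0 < 0:
            raise DomainError(f"u0 must be >= 0, got {self.u0}")
        if self.d < 0:
            raise DomainError(f"decay rate d must be >= 0, got {self.d}")
        if not (self.m > 0):
            raise DomainError(f"pharmacokinetic exponent m must be > 0, got {self.m}")
        if self.a_N < 0 or self.a_T < 0:
            raise DomainError("response coefficients a_N, a_T must be >= 0")
        if self.t_rx < 0:
            raise DomainError(f"therapy start t_rx must be >= 0, got {self.t_rx}")
        for name in ("lumped_kill_N", "lumped_kill_T"):
            val = getattr(self, name)
            if val is not None:
                if self.mode != "static":
                    raise ConfigError(f"{name} is only valid with mode='static'")
                if val < 0:
                    raise DomainError(f"{name} must be >= 0, got {val}")

    def with_start(self, t_rx: float) -> "DrugProgram":
        """Copy with the therapy start time replaced (trigger resolution)."""
        return dataclasses.replace(self, t_rx=t_rx)

    def static_kill_constants(self) -> Tuple[float, float]:
        """Resolved constant per-capita kills for static mode."""
        kN = (
            self.lumped_kill_N
            if self.lumped_kill_N is not None
            else kill_rate(self.u0, self.a_N, self.m)
        )
        kT = (
            self.lumped_kill_T
            if self.lumped_kill_T is not None
            else kill_rate(self.u0, self.a_T, self.m)
        )
        return kN, kT

    def percapita_kill(self, t: float) -> Tuple[float, float]:
        """Per-capita kill rates (kill_N, kill_T) at time ``t``, 1/time."""
        if self.mode == "none" or t < self.t_rx:
            return 0.0, 0.0
        if self.mode == "static":
            return self.static_kill_constants()
        u = drug_level(t, self)
        return kill_rate(u, self.a_N, self.m), kill_rate(u, self.a_T, self.m)


def drug_level(t: float, prog: DrugProgram) -> float:
    """Drug amount u(t) at the tumor site.

    0 before therapy start and for mode ``"none"``; ``u0`` for static;
    ``u0 * exp(-d * (t - t_rx))`` for exponential decay.  Non-increasing
    after ``t_rx``.
    """
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    if prog.mode == "none" or t < prog.t_rx:
        return 0.0
    if prog.mode == "static":
        return prog.u0
    return prog.u0 * math.exp(-prog.d * (t - prog.t_rx))


def kill_rate(u: float, a: float, m: float = 1.0) -> float:
    """Fractional-cell-kill response ``a * (1 - exp(-m*u))``, 1/time.

    Zero at ``u = 0``, strictly increasing in ``u``, asymptote ``a``.
    """
    if u < 0:
        raise DomainError(f"drug amount must be >= 0, got {u}")
    return -a * math.expm1(-m * u)
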