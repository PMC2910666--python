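"""Intrinsic single-population growth laws.

The package models every uncoupled compartment with the Richards
(generalized-logistic) family

    dx/dt = (r / nu) * x * (1 - (x / K)**nu),    nu > 0,

whose ``nu -> 0`` limit is the Gompertz law ``dx/dt = r * x * ln(K / x)``
and whose ``nu = 1`` member is the plain logistic equation.  ``r`` is the
intrinsic per-capita rate (1/time), ``K`` the carrying capacity / asymptotic
plateau (cells), and ``nu`` a dimensionless shape exponent.

Both the flux and the closed-form solution are exposed: the flux feeds the
coupled ODE right-hand side, while the closed form serves as an independent
analytic oracle for the numerical integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["GrowthLaw", "generalized_growth_flux", "closed_form_population"]


@dataclass(frozen=True)
class GrowthLaw:
    """Parameters of one compartment's intrinsic growth.

    Attributes
    ----------
    rate : float
        Intrinsic per-capita growth coefficient, 1/time (> 0).
    capacity : float
        Carrying capacity / asymptotic plateau, cells (> 0).
    shape : float
        Shape exponent ``nu`` (>= 0); 0 encodes the Gompertz limit,
        1 the logistic law.
    """

    rate: float
    capacity: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rate > 0):
            raise DomainError(f"growth rate must be > 0, got {self.rate}")
        if not (self.capacity > 0):
            raise DomainError(f"capacity must be > 0, got {self.capacity}")
        if not (self.shape >= 0):
            raise DomainError(f"shape exponent must be >= 0, got {self.shape}")

    def flux(self, x):
        return generalized_growth_flux(x, self)

    def solution(self, x0, t):
        return closed_form_population(self, x0, t)


def generalized_growth_flux(x, law: GrowthLaw):
    """Growth flux dx/dt of the generalized-logistic family, cells/time.

    ``(rate/nu) * x * (1 - (x/capacity)**nu)`` for ``nu > 0``; the continuous
    limit ``rate * x * ln(capacity/x)`` for ``nu = 0``.  ``x = 0`` and
    ``x = capacity`` are fixed points for every shape (the Gompertz flux at 0
    is defined as 0 by continuity).

    Accepts scalars or arrays; raises :class:`DomainError` on negative ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError("population size must be non-negative")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    pos = arr > 0
    xp = arr[pos]
    if law.shape == 0:
        out[pos] = law.rate * xp * np.log(law.capacity / xp)
    else:
        # expm1 keeps the nu -> 0 limit numerically exact for tiny nu
        out[pos] = -(law.rate / law.shape) * xp * np.expm1(
            law.shape * np.log(xp / law.capacity)
        )
    return float(out[0]) if scalar else out


def closed_form_population(law: GrowthLaw, x0: float, t):
    """Analytic solution x(t) of the growth law from ``x(0) = x0 > 0``.

    For ``nu > 0``:  ``K * [1 + ((K/x0)**nu - 1) * exp(-r t)]**(-1/nu)``;
    for ``nu = 0`` (Gompertz):  ``K * exp(ln(x0/K) * exp(-r t))``.

    Monotone toward the capacity, which it approaches as ``t -> inf``.
    """
    if not (x0 > 0):
        raise DomainError(f"initial population must be > 0, got {x0}")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise DomainError("time must be non-negative")
    decay = np.exp(-law.rate * tt)
    if law.shape == 0:
        out = law.capacity * np.exp(math.log(x0 / law.capacity) * decay)
    else:
        # c = (K/x0)**nu - 1 via expm1/log1p for stability at tiny nu
        c = math.expm1(law.shape * math.log(law.capacity / x0))
        out = law.capacity * np.exp(-np.log1p(c * decay) / law.shape)
    return float(out) if out.ndim == 0 else out
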