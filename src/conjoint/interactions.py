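"""Bidirectional normal-tumor coupling rules.

Tumor cells secrete a growth-modification factor (GMF) that stimulates
normal-cell proliferation while the tumor is below a critical size ``T*``
and inhibits / kills normal cells once the tumor exceeds it.  Normal cells
in turn restrain tumor growth, but only up to a saturating ceiling.

Two modification fluxes (cells/time) are added to the uncoupled growth laws:

* ``normal_modifier`` — the GMF effect on the normal compartment,
  ``f_N(T) * N`` with ``f_N(T) = beta * (T/k_scale) * (1 - T/t_crit) *
  (T / (rho1 + T))``.  Zero at ``T = 0`` and exactly at ``T = t_crit``;
  positive (stimulation) below the critical size, negative (inhibition)
  above it; proportional to ``N``.
* ``tumor_modifier`` — normal-cell suppression of the tumor,
  ``-k * (N / (rho0 + N)) * (T / (rho1 + T))``, which saturates at the
  constant ceiling ``k`` for large ``N`` and vanishes with either population.

A Hill-type variant of the normal-cell rule with the same zeros and sign
structure is available for sensitivity analysis.  With ``beta = k = 0`` the
system decouples exactly into the two intrinsic growth laws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError, DomainError

__all__ = [
    "InteractionParams",
    "normal_modifier",
    "tumor_modifier",
    "hill_normal_modifier",
    "normal_coupling_flux",
]

_VARIANTS = ("default", "hill")


@dataclass(frozen=True)
class InteractionParams:
    """Coupling parameters between the normal and tumor compartments.

    Attributes
    ----------
    beta : float
        Stimulation/inhibition coefficient of the GMF effect, 1/time (>= 0).
    k : float
        Saturating suppression ceiling of normal cells on the tumor,
        cells/time (>= 0).
    t_crit : float
        Critical tumor size ``T*`` at which the GMF effect switches sign,
        cells (> 0).
    rho0 : float
        Half-saturation of the normal-cell effect on the tumor, cells (> 0).
    rho1 : float
        Half-saturation in tumor size for both rules, cells (> 0).
    k_scale : float, optional
        Tumor-size normalization of the GMF rule, cells (> 0).  When left
        ``None`` the model assembly substitutes the tumor carrying capacity
        of the active scenario.
    hill_m : int, optional
        Hill degree for the variant normal-cell rule (>= 1).
    variant : str
        Active normal-cell rule: ``"default"`` or ``"hill"``.
    """

    beta: float = 0.0
    k: float = 0.0
    t_crit: float = 3e5
    rho0: float = 1.0
    rho1: float = 1000.0
    k_scale: Optional[float] = None
    hill_m: Optional[int] = None
    variant: str = "default"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise DomainError(f"beta must be >= 0, got {self.beta}")
        if self.k < 0:
            raise DomainError(f"k must be >= 0, got {self.k}")
        if not (self.t_crit > 0):
            raise DomainError(f"t_crit must be > 0, got {self.t_crit}")
        if not (self.rho0 > 0):
            raise DomainError(f"rho0 must be > 0, got {self.rho0}")
        if not (self.rho1 > 0):
            raise DomainError(f"rho1 must be > 0, got {self.rho1}")
        if self.k_scale is not None and not (self.k_scale > 0):
            raise DomainError(f"k_scale must be > 0, got {self.k_scale}")
        if self.variant not in _VARIANTS:
            raise ConfigError(
                f"unknown interaction variant {self.variant!r}; "
                f"choose from {_VARIANTS}"
            )
        if self.variant == "hill":
            if self.hill_m is None or self.hill_m < 1:
                raise ConfigError(
                    f"hill variant requires hill_m >= 1, got {self.hill_m}"
                )


def _check_populations(N: float, T: float) -> None:
    if N < 0 or T < 0:
        raise DomainError(f"populations must be non-negative, got N={N}, T={T}")


def normal_modifier(N: float, T: float, p: InteractionParams) -> float:
    """GMF flux on the normal compartment, cells/time.

    Positive for ``0 < T < t_crit`` (stimulation), zero at ``T = 0`` and
    ``T = t_crit``, negative for ``T > t_crit`` (inhibition/kill);
    proportional to ``N``.
    """
    _check_populations(N, T)
    if p.k_scale is None:
        raise ConfigError("k_scale unresolved; set it or assemble via ModelSpec")
    if T == 0.0 or N == 0.0:
        return 0.0
    return (
        p.beta
        * N
        * (T / p.k_scale)
        * (1.0 - T / p.t_crit)
        * (T / (p.rho1 + T))
    )


def tumor_modifier(N: float, T: float, p: InteractionParams) -> float:
    """Normal-cell suppression flux on the tumor, cells/time (always <= 0).

    Saturates at the ceiling ``k`` as ``N`` grows ("constant effect") and
    vanishes when either population is absent.
    """
    _check_populations(N, T)
    if N == 0.0 or T == 0.0:
        return 0.0
    return -p.k * (N / (p.rho0 + N)) * (T / (p.rho1 + T))


def hill_normal_modifier(N: float, T: float, p: InteractionParams) -> float:
    """Hill-degree-``m`` variant of the GMF rule on normal cells.

    ``beta * N * (T**m / (rho1**m + T**m)) * (1 - (T/t_crit)**m)`` — same
    zeros (``T = 0``, ``T = t_crit``) and sign structure for every degree.
    """
    _check_populations(N, T)
    if p.hill_m is None or p.hill_m < 1:
        raise ConfigError(f"hill_m must be >= 1, got {p.hill_m}")
    if T == 0.0 or N == 0.0:
        return 0.0
    m = p.hill_m
    tm = T**m
    return p.beta * N * (tm / (p.rho1**m + tm)) * (1.0 - (T / p.t_crit) ** m)


def normal_coupling_flux(N: float, T: float, p: InteractionParams) -> float:
    """Dispatch the active normal-cell rule (``variant`` field)."""
    if p.variant == "hill":
        return hill_normal_modifier(N, T, p)
    return normal_modifier(N, T, p)
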