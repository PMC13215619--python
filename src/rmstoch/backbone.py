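"""Deterministic Rosenzweig-MacArthur backbone.

The nondimensional R-M system with Holling type II predation,

    dN/dt = N (1 - N/k) - m N P / (1 + N),
    dP/dt = P (-c + m N / (1 + N)),

has three equilibria: total extinction ``K1 = (0, 0)``, prey-only
``K2 = (k, 0)``, and (when feasible) the coexistence state

    K3 = ( c/(m-c),  (k(m-c) - c) / (k (m-c)^2) ).

``K3`` lies in the open quadrant D = (0, inf)^2 iff ``m > c`` and
``k (m - c) > c``.  At ``K3`` the Jacobian determinant is positive, so
stability is decided by the trace, which changes sign at the
enrichment-driven Hopf threshold ``k_H = (m + c) / (m - c)``: the
coexistence equilibrium is stable for ``k < k_H`` (regime Lambda2) and
surrounded by a limit cycle for ``k > k_H`` (regime Lambda1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "EquilibriumSet",
    "Regime",
    "equilibria",
    "jacobian",
    "hopf_threshold",
    "classify_regime",
    "in_interior",
    "validate_state",
]


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the stochastic R-M model.

    Parameters
    ----------
    m : float
        Maximum predation/assimilation rate (> 0).
    c : float
        Predator per-capita mortality (> 0).
    k : float
        Prey carrying capacity (> 0).
    e : float, default 1.0
        Predation-to-offspring conversion probability, in (0, 1].  The
        reduced nondimensional backbone corresponds to ``e = 1``.
    omega : float, default 1.0
        System size (habitat scale) linking counts to densities
        ``x = X / omega``; demographic noise variance scales as 1/omega.
    """

    m: float
    c: float
    k: float
    e: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if not (self.m > 0 and math.isfinite(self.m)):
            raise ValueError(f"m must be positive, got {self.m}")
        if not (self.c > 0 and math.isfinite(self.c)):
            raise ValueError(f"c must be positive, got {self.c}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be positive, got {self.k}")
        if not (0 < self.e <= 1):
            raise ValueError(f"e must lie in (0, 1], got {self.e}")
        if not (self.omega > 0 and math.isfinite(self.omega)):
            raise ValueError(f"omega must be positive, got {self.omega}")

    @property
    def coexistence_feasible(self) -> bool:
        """True iff the coexistence equilibrium K3 lies in D (strict)."""
        return self.m > self.c and self.k * (self.m - self.c) > self.c


def in_interior(x) -> bool:
    """Membership predicate for the open quadrant D = (0, inf)^2."""
    n, p = float(x[0]), float(x[1])
    return n > 0.0 and p > 0.0


def validate_state(x, *, allow_boundary: bool = True) -> np.ndarray:
    """Coerce ``x`` to a length-2 float array and check nonnegativity."""
    arr = np.asarray(x, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"state must be a pair (N, P), got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"state components must be nonnegative, got {arr}")
    if not allow_boundary and not in_interior(arr):
        raise ValueError(f"state must lie in the open quadrant D, got {arr}")
    return arr


@dataclass(frozen=True)
class EquilibriumSet:
    """The three R-M equilibria; ``K3`` is None when coexistence is infeasible."""

    K1: tuple[float, float]
    K2: tuple[float, float]
    K3: tuple[float, float] | None = field(default=None)


def equilibria(params: ModelParams) -> EquilibriumSet:
    """Equilibria of the deterministic backbone.

    ``K1 = (0, 0)`` and ``K2 = (k, 0)`` always exist; the coexistence
    state ``K3`` is reported only when it lies strictly inside D.
    """
    k3 = None
    if params.coexistence_feasible:
        d = params.m - params.c
        n_star = params.c / d
        p_star = (params.k * d - params.c) / (params.k * d * d)
        k3 = (n_star, p_star)
    return EquilibriumSet(K1=(0.0, 0.0), K2=(params.k, 0.0), K3=k3)


def jacobian(params: ModelParams, x) -> np.ndarray:
    """Jacobian of the R-M vector field at a state ``x = (N, P)``."""
    n, p = validate_state(x)
    m, c, k = params.m, params.c, params.k
    denom = 1.0 + n
    return np.array(
        [
            [1.0 - 2.0 * n / k - m * p / denom**2, -m * n / denom],
            [m * p / denom**2, -c + m * n / denom],
        ]
    )


def hopf_threshold(m: float, c: float) -> float:
    """Carrying capacity at which K3 loses stability: ``(m + c)/(m - c)``.

    Raises
    ------
    ValueError
        If ``m <= c`` (no coexistence for any k, threshold undefined).
    """
    if not m > c:
        raise ValueError(f"Hopf threshold requires m > c, got m={m}, c={c}")
    return (m + c) / (m - c)


class Regime(enum.Enum):
    """Parameter regimes organized by the Hopf threshold."""

    LAMBDA1 = "Lambda1"  # k > k_H: oscillatory (limit cycle)
    LAMBDA2 = "Lambda2"  # k < k_H: stable coexistence
    THRESHOLD = "threshold"  # |k - k_H| within root tolerance
    INFEASIBLE = "infeasible"  # K3 absent


#: relative tolerance for declaring k to sit exactly on the Hopf threshold
_HOPF_RTOL = 1e-12


def classify_regime(params: ModelParams) -> Regime:
    """Classify ``params`` relative to the Hopf threshold."""
    if not params.coexistence_feasible:
        return Regime.INFEASIBLE
    k_h = hopf_threshold(params.m, params.c)
    if abs(params.k - k_h) <= _HOPF_RTOL * k_h:
        return Regime.THRESHOLD
    return Regime.LAMBDA2 if params.k < k_h else Regime.LAMBDA1
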