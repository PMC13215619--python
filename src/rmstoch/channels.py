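"""Generic stoichiometry engine and the three drift-compatible predation closures.

A :class:`ChannelSystem` pairs a stoichiometric matrix ``S`` (columns are
per-event increments ``nu_k``) with density-level intensity functions
``f(x)``.  Both the deterministic drift and the demographic diffusion
covariance derive from this single object:

    b(x) = S f(x),          a(x) = (1/Omega) S diag(f(x)) S^T.

The three built-in predation closures share the same drift but differ at
second order:

* ``bernoulli`` -- the exact mechanism: a predation encounter followed by
  Bernoulli conversion with success probability ``e``; channels
  ``(-1, +1)`` at rate ``e f_pred`` and ``(-1, 0)`` at rate ``(1-e) f_pred``.
* ``effective`` -- one density-level channel ``(-1, e)`` at rate ``f_pred``
  (diffusion-only; not an integer CTMC jump for e < 1).
* ``split`` -- prey loss ``(-1, 0)`` at rate ``f_pred`` and predator gain
  ``(0, +1)`` at rate ``e f_pred``: the drift-matched diagonal-noise
  comparator.

Coupled closures (bernoulli, effective) produce a strictly negative
predator-prey cross-covariance ``a12 = -e f_pred / Omega`` on the interior;
the split closure has ``a12 = 0``.  The non-predation channels (prey birth,
prey competition death, predator death) contribute only diagonal terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .backbone import ModelParams, in_interior, validate_state

__all__ = [
    "ChannelSystem",
    "CovarianceReport",
    "CLOSURES",
    "build_channels",
    "drift",
    "diffusion_matrix",
    "cross_cov_ratio",
    "factorize",
    "holling2_predation",
]

CLOSURES = ("bernoulli", "effective", "split")

#: number of non-predation (base) channels shared by all built-in closures
_N_BASE = 3


def holling2_predation(m: float):
    """Holling type II predation intensity ``f_pred(x) = m N P / (1 + N)``."""

    def f_pred(x):
        n, p = x
        return m * n * p / (1.0 + n)

    return f_pred


@dataclass(frozen=True)
class ChannelSystem:
    """A stoichiometric matrix paired with its intensity evaluator.

    Attributes
    ----------
    closure_name : str
        One of ``bernoulli``/``effective``/``split`` for built-in systems,
        or any label for a user-supplied (S, f) pair.
    S : ndarray, shape (d, K)
        Stoichiometric increments, one column per channel.
    intensities : callable
        ``f(x) -> (K,) array`` of nonnegative density-level rates.
    params : ModelParams or None
        Model parameters for built-in closures (None for custom systems).
    n_pred : int
        Number of trailing channels forming the predation block (used for
        the base/predation covariance decomposition; 0 if unknown).
    """

    closure_name: str
    S: np.ndarray
    intensities: Callable[[Sequence[float]], np.ndarray]
    params: ModelParams | None = None
    n_pred: int = 0

    @property
    def K(self) -> int:
        return self.S.shape[1]

    @property
    def dim(self) -> int:
        return self.S.shape[0]

    @property
    def integer_jumps(self) -> bool:
        """True iff every stoichiometric increment is integer-valued."""
        return bool(np.all(self.S == np.round(self.S)))

    def f(self, x) -> np.ndarray:
        """Evaluate intensities, enforcing componentwise nonnegativity."""
        vals = np.asarray(self.intensities(x), dtype=float)
        if vals.shape != (self.K,):
            raise ValueError(
                f"intensity evaluator returned shape {vals.shape}, expected ({self.K},)"
            )
        if np.any(vals < 0):
            raise ValueError(f"negative intensity at state {x}: {vals}")
        return vals

    @staticmethod
    def custom(S, intensities, name: str = "custom", n_pred: int = 0) -> "ChannelSystem":
        """Wrap an arbitrary (S, f) pair (the five-step generalization recipe)."""
        S = np.atleast_2d(np.asarray(S, dtype=float))
        return ChannelSystem(
            closure_name=name, S=S, intensities=intensities, n_pred=n_pred
        )


def _base_intensities(params: ModelParams, x) -> tuple[float, float, float]:
    n, p = float(x[0]), float(x[1])
    return n, n * n / params.k, params.c * p


def build_channels(params: ModelParams, closure: str = "bernoulli") -> ChannelSystem:
    """Construct the built-in R-M channel system for the given closure.

    All closures share the base channels prey birth ``(+1, 0)`` at rate
    ``N``, prey competition death ``(-1, 0)`` at rate ``N^2/k`` and
    predator death ``(0, -1)`` at rate ``c P``, followed by the
    closure-specific predation channels.
    """
    if not isinstance(params, ModelParams):
        raise TypeError("params must be a ModelParams instance")
    if closure not in CLOSURES:
        raise ValueError(f"unknown closure {closure!r}; expected one of {CLOSURES}")

    m, e = params.m, params.e
    base_cols = [(1.0, 0.0), (-1.0, 0.0), (0.0, -1.0)]
    fp = holling2_predation(m)

    if closure == "bernoulli":
        cols = base_cols + [(-1.0, 1.0), (-1.0, 0.0)]

        def intens(x, params=params, fp=fp, e=e):
            f1, f2, f3 = _base_intensities(params, x)
            fpred = fp(x)
            return np.array([f1, f2, f3, e * fpred, (1.0 - e) * fpred])

        n_pred = 2
    elif closure == "effective":
        cols = base_cols + [(-1.0, e)]

        def intens(x, params=params, fp=fp):
            f1, f2, f3 = _base_intensities(params, x)
            return np.array([f1, f2, f3, fp(x)])

        n_pred = 1
    else:  # split
        cols = base_cols + [(-1.0, 0.0), (0.0, 1.0)]

        def intens(x, params=params, fp=fp, e=e):
            f1, f2, f3 = _base_intensities(params, x)
            fpred = fp(x)
            return np.array([f1, f2, f3, fpred, e * fpred])

        n_pred = 2

    S = np.array(cols, dtype=float).T
    return ChannelSystem(
        closure_name=closure, S=S, intensities=intens, params=params, n_pred=n_pred
    )


def drift(cs: ChannelSystem, x) -> np.ndarray:
    """Deterministic drift ``b(x) = S f(x)`` (identical across closures)."""
    x = validate_state(x)
    return cs.S @ cs.f(x)


@dataclass(frozen=True)
class CovarianceReport:
    """Diffusion covariance at a state, with its predation decomposition.

    ``a = a_base + a_pred`` where the base part (non-predation channels)
    is diagonal; ``rho = a12 / sqrt(a11 a22)`` is the signed normalized
    cross-covariance (NaN on the boundary where a variance vanishes);
    ``sigma`` satisfies ``sigma sigma^T = a``.
    """

    state: tuple[float, float]
    a: np.ndarray
    a_base: np.ndarray
    a_pred: np.ndarray
    rho: float
    sigma: np.ndarray


def diffusion_matrix(cs: ChannelSystem, x) -> CovarianceReport:
    """Diffusion covariance ``a(x) = (1/Omega) S diag(f(x)) S^T``.

    The report splits ``a`` into the diagonal base part and the
    closure-dependent predation block, and includes the signed ratio
    ``rho`` plus a semidefinite-safe square root.
    """
    x = validate_state(x)
    omega = cs.params.omega if cs.params is not None else 1.0
    f = cs.f(x)
    a = (cs.S * f) @ cs.S.T / omega

    n_pred = cs.n_pred
    if n_pred > 0:
        s_pred = cs.S[:, cs.K - n_pred :]
        a_pred = (s_pred * f[cs.K - n_pred :]) @ s_pred.T / omega
    else:
        a_pred = np.zeros_like(a)
    a_base = a - a_pred

    if a[0, 0] > 0 and a[1, 1] > 0:
        rho = float(a[0, 1] / np.sqrt(a[0, 0] * a[1, 1]))
    else:
        rho = float("nan")

    sigma = factorize(a, method="cholesky")
    return CovarianceReport(
        state=(float(x[0]), float(x[1])),
        a=a,
        a_base=a_base,
        a_pred=a_pred,
        rho=rho,
        sigma=sigma,
    )


def cross_cov_ratio(cs: ChannelSystem, x) -> float:
    """Signed normalized cross-covariance ``rho = a12 / sqrt(a11 a22)``.

    Independent of Omega (the 1/Omega factor cancels).  Raises on boundary
    states where a marginal variance vanishes.
    """
    x = validate_state(x)
    if not in_interior(x):
        raise ValueError(f"rho is undefined on the boundary, got state {tuple(x)}")
    rep = diffusion_matrix(cs, x)
    a = rep.a
    if not (a[0, 0] > 0 and a[1, 1] > 0):
        raise ValueError(f"rho undefined: vanishing variance at state {tuple(x)}")
    return float(a[0, 1] / np.sqrt(a[0, 0] * a[1, 1]))


#: relative tolerance on the reconstruction sigma sigma^T = a
_FACTOR_TOL = 1e-12


def factorize(
    a,
    method: str = "cholesky",
    cs: ChannelSystem | None = None,
    x=None,
) -> np.ndarray:
    """Square root ``sigma`` of a symmetric PSD matrix with ``sigma sigma^T = a``.

    Parameters
    ----------
    method : {"cholesky", "event"}
        ``cholesky`` returns the 2x2 lower-triangular factor (falling back
        to an eigenvalue-clipped symmetric root when ``a`` is singular,
        as happens at boundary states where demographic intensities
        vanish).  ``event`` returns the channel-semantics factor
        ``(1/sqrt(Omega)) S diag(sqrt(f(x)))`` of shape (2, K) and
        requires ``cs`` and ``x``.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix must be square, got shape {a.shape}")
    scale = max(1.0, float(np.max(np.abs(a))))
    if np.max(np.abs(a - a.T)) > _FACTOR_TOL * scale:
        raise ValueError("matrix is not symmetric")

    if method == "event":
        if cs is None or x is None:
            raise ValueError("event factorization requires a ChannelSystem and a state")
        omega = cs.params.omega if cs.params is not None else 1.0
        f = cs.f(validate_state(x))
        sigma = cs.S * np.sqrt(f) / np.sqrt(omega)
    elif method == "cholesky":
        w = np.linalg.eigvalsh(a)
        if w[0] < -_FACTOR_TOL * scale:
            raise ValueError(f"matrix is not PSD (min eigenvalue {w[0]:.3e})")
        try:
            sigma = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            # boundary states: clip tiny negative eigenvalues, symmetric root
            w, v = np.linalg.eigh(a)
            sigma = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    else:
        raise ValueError(f"unknown factorization method {method!r}")

    if np.max(np.abs(sigma @ sigma.T - a)) > _FACTOR_TOL * scale:
        raise ValueError("factorization failed its reconstruction tolerance")
    return sigma
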