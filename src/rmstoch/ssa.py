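"""Exact integer-valued CTMC simulation (Gillespie direct method).

Counts ``X = (XN, XP)`` evolve by the jump channels of a
:class:`~rmstoch.channels.ChannelSystem` with density-dependent
(Kurtz-type) propensities ``lambda_k(X) = Omega f_k(X / Omega)``.
Waiting times are exponential with rate ``sum_k lambda_k`` and the firing
channel is chosen proportionally to its propensity, so trajectories are
exact samples of the jump process described by the chemical master
equation.  Short-window increment moments estimated here test the exact
identities  E[dX] = sum_k lambda_k nu_k dt  and
Cov(dX) = S diag(lambda) S^T dt.

The effective closure (real-valued jump ``(-1, e)``) is a diffusion-level
object and is categorically refused here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .channels import ChannelSystem

__all__ = [
    "SSAConfig",
    "CountTrajectory",
    "ExtinctionRecord",
    "propensities",
    "ssa_trajectory",
    "empirical_increment_moments",
    "IncrementMoments",
    "batch_extinction",
]

_FACE_NAMES = {0: "none", 1: "N", 2: "P", 3: "corner"}
_TERM_NAMES = {0: "t_max", 1: "max_events", 2: "frozen"}


@dataclass(frozen=True)
class SSAConfig:
    """Configuration of one SSA run."""

    t_max: float
    seed: int
    max_events: int = 1_000_000
    record_mode: str = "full"  # "full" or "thinned"
    thin_dt: float | None = None

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")
        if self.record_mode not in ("full", "thinned"):
            raise ValueError(f"unknown record_mode {self.record_mode!r}")
        if self.record_mode == "thinned" and not (self.thin_dt and self.thin_dt > 0):
            raise ValueError("thinned recording requires a positive thin_dt")


@dataclass
class CountTrajectory:
    """A recorded SSA path.

    ``states[i+1] = states[i] + nu_{events[i+1]}`` for full recordings;
    thinned recordings hold last-observation-carried-forward states on a
    uniform grid (events not retained).  Once both counts hit zero the
    process is frozen and no further events occur.
    """

    times: np.ndarray
    states: np.ndarray  # (n, 2) integer counts
    events: np.ndarray  # channel index 1..K per jump, 0 for the initial row
    terminal_reason: str
    first_face: str = "none"
    first_face_time: float | None = None
    seed: int | None = None
    omega: float = 1.0
    closure: str = ""


def _require_integer_ctmc(cs: ChannelSystem) -> None:
    if cs.closure_name == "effective":
        raise ValueError(
            "the effective (-1, e) closure is a diffusion-level object, "
            "not an admissible exact CTMC jump; use bernoulli or split"
        )
    if not cs.integer_jumps:
        raise ValueError("SSA requires an integer-valued stoichiometric matrix")


def _counts(X) -> np.ndarray:
    arr = np.asarray(X)
    if arr.shape != (2,):
        raise ValueError("counts must be a pair (XN, XP)")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError(f"counts must be nonnegative integers, got {X}")
    return arr.astype(np.int64)


def propensities(cs: ChannelSystem, X, omega: float | None = None) -> np.ndarray:
    """Count-level propensities ``lambda_k = Omega f_k(X / Omega)``."""
    _require_integer_ctmc(cs)
    X = _counts(X)
    if omega is None:
        omega = cs.params.omega if cs.params is not None else 1.0
    return omega * cs.f(X / omega)


def _seed32(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def ssa_trajectory(
    cs: ChannelSystem,
    X0,
    omega: float | None = None,
    config: SSAConfig | None = None,
) -> CountTrajectory:
    """Simulate one exact CTMC path with the Gillespie direct method.

    Deterministic given ``config.seed``; stops at ``t_max``,
    ``max_events`` or total extinction (frozen at ``(0, 0)``).
    """
    _require_integer_ctmc(cs)
    if config is None:
        raise ValueError("an SSAConfig is required")
    X0 = _counts(X0)
    if omega is None:
        omega = cs.params.omega if cs.params is not None else 1.0

    if cs.params is not None and cs.closure_name in ("bernoulli", "split"):
        traj = _ssa_builtin(cs, X0, omega, config)
    else:
        traj = _ssa_generic(cs, X0, omega, config)

    if config.record_mode == "thinned":
        traj = _thin(traj, config.thin_dt, config.t_max)
    return traj


def _ssa_builtin(cs, X0, omega, config) -> CountTrajectory:
    p = cs.params
    code = _kernels.CLOSURE_CODES[cs.closure_name]
    cap = config.max_events + 1
    rec_t = np.empty(cap)
    rec_xn = np.empty(cap, dtype=np.int64)
    rec_xp = np.empty(cap, dtype=np.int64)
    rec_ev = np.empty(cap, dtype=np.int64)
    n_rec, term, _, _, _, face, face_time, _ = _kernels.ssa_core(
        code,
        p.m,
        p.c,
        p.k,
        p.e,
        float(omega),
        int(X0[0]),
        int(X0[1]),
        float(config.t_max),
        int(config.max_events),
        _seed32(config.seed),
        True,
        rec_t,
        rec_xn,
        rec_xp,
        rec_ev,
        False,
    )
    states = np.column_stack([rec_xn[:n_rec], rec_xp[:n_rec]])
    return CountTrajectory(
        times=rec_t[:n_rec].copy(),
        states=states,
        events=rec_ev[:n_rec].copy(),
        terminal_reason=_TERM_NAMES[term],
        first_face=_FACE_NAMES[face],
        first_face_time=None if face == 0 else float(face_time),
        seed=config.seed,
        omega=float(omega),
        closure=cs.closure_name,
    )


def _ssa_generic(cs, X0, omega, config) -> CountTrajectory:
    """Pure-Python direct method for arbitrary integer (S, f) systems."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    S = cs.S.astype(np.int64)
    X = X0.astype(np.int64).copy()
    t = 0.0
    times = [0.0]
    states = [X.copy()]
    events = [0]
    term = "t_max"
    n_events = 0
    while True:
        lam = omega * cs.f(X / omega)
        tot = float(lam.sum())
        if tot <= 0.0:
            term = "frozen"
            break
        if n_events >= config.max_events:
            term = "max_events"
            break
        t_next = t + rng.exponential(1.0 / tot)
        if t_next > config.t_max:
            break
        t = t_next
        kx = int(rng.choice(cs.K, p=lam / tot))
        X = X + S[:, kx]
        if np.any(X < 0):  # propensities must vanish before this can happen
            raise RuntimeError("SSA produced a negative count; invalid (S, f) pair")
        n_events += 1
        times.append(t)
        states.append(X.copy())
        events.append(kx + 1)
    return CountTrajectory(
        times=np.array(times),
        states=np.array(states, dtype=np.int64),
        events=np.array(events, dtype=np.int64),
        terminal_reason=term,
        seed=config.seed,
        omega=float(omega),
        closure=cs.closure_name,
    )


def _thin(traj: CountTrajectory, dt: float, t_max: float) -> CountTrajectory:
    grid = np.arange(0.0, t_max + dt / 2, dt)
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    return CountTrajectory(
        times=grid,
        states=traj.states[idx],
        events=np.zeros(len(grid), dtype=np.int64),
        terminal_reason=traj.terminal_reason,
        first_face=traj.first_face,
        first_face_time=traj.first_face_time,
        seed=traj.seed,
        omega=traj.omega,
        closure=traj.closure,
    )


@dataclass(frozen=True)
class IncrementMoments:
    """Monte-Carlo estimates of short-window count increment moments."""

    mean: np.ndarray
    cov: np.ndarray
    mean_se: np.ndarray
    cov_se: np.ndarray
    n_rep: int
    dt: float


def empirical_increment_moments(
    cs: ChannelSystem,
    X,
    omega: float | None = None,
    dt: float = 1e-3,
    n_rep: int = 100_000,
    seed: int = 0,
) -> IncrementMoments:
    """Estimate E[dX] and Cov(dX) over ``n_rep`` windows of length ``dt``.

    Each window starts from the same count state ``X`` and evolves by the
    exact CTMC; the estimates converge to ``sum_k lambda_k nu_k dt`` and
    ``S diag(lambda) S^T dt`` as ``dt -> 0``.
    """
    _require_integer_ctmc(cs)
    if n_rep < 100:
        raise ValueError("n_rep < 100 gives meaningless standard errors")
    X = _counts(X)
    if omega is None:
        omega = cs.params.omega if cs.params is not None else 1.0
    lam0 = propensities(cs, X, omega)
    if dt * lam0.sum() > 0.1:
        warnings.warn(
            f"dt * total propensity = {dt * lam0.sum():.3g} > 0.1; the "
            "first-order window approximation may be poor",
            stacklevel=2,
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x494D]))
    S = cs.S.astype(np.int64)
    dX = np.zeros((n_rep, 2), dtype=np.int64)
    t = np.zeros(n_rep)
    active = np.arange(n_rep)
    while active.size:
        states = X[None, :] + dX[active]
        lam = np.stack([omega * cs.f(s / omega) for s in states]) \
            if cs.params is None else _lam_builtin(cs, states, omega)
        tot = lam.sum(axis=1)
        alive = tot > 0
        active = active[alive]
        if not active.size:
            break
        lam, tot = lam[alive], tot[alive]
        t[active] += rng.exponential(1.0 / tot)
        inside = t[active] <= dt
        active = active[inside]
        if not active.size:
            break
        lam, tot = lam[inside], tot[inside]
        u = rng.random(active.size) * tot
        ks = (np.cumsum(lam, axis=1) < u[:, None]).sum(axis=1)
        dX[active] += S[:, ks].T

    d = dX.astype(float)
    mean = d.mean(axis=0)
    cov = np.cov(d.T, bias=False)
    mean_se = d.std(axis=0, ddof=1) / np.sqrt(n_rep)
    centered = d - mean
    prod = centered[:, :, None] * centered[:, None, :]
    cov_se = prod.std(axis=0, ddof=1) / np.sqrt(n_rep)
    return IncrementMoments(
        mean=mean, cov=np.atleast_2d(cov), mean_se=mean_se, cov_se=cov_se,
        n_rep=n_rep, dt=dt,
    )


def _lam_builtin(cs: ChannelSystem, states: np.ndarray, omega: float) -> np.ndarray:
    """Vectorized propensities for the built-in closures, states shape (n, 2)."""
    p = cs.params
    N = states[:, 0] / omega
    P = states[:, 1] / omega
    fp = p.m * N * P / (1.0 + N)
    base = [N, N * N / p.k, p.c * P]
    if cs.closure_name == "bernoulli":
        cols = base + [p.e * fp, (1.0 - p.e) * fp]
    else:  # split
        cols = base + [fp, p.e * fp]
    return omega * np.column_stack(cols)


@dataclass(frozen=True)
class ExtinctionRecord:
    """Outcome of one absorbed SSA replicate."""

    replicate: int
    seed: int
    extinction_time: float | None  # None when censored at t_max
    boundary: str  # "N", "P", "corner" or "none"
    censored: bool


def batch_extinction(
    cs: ChannelSystem,
    X0,
    omega: float | None = None,
    config: SSAConfig | None = None,
    n: int = 100,
) -> list[ExtinctionRecord]:
    """Run ``n`` independent SSA replicates and record first boundary hits.

    The extinction time of a replicate is the first time either count
    reaches zero (the face is recorded); replicates still interior at
    ``t_max`` are censored.  Replicate streams derive from
    ``(config.seed, replicate)`` so batches are order-independent.
    """
    _require_integer_ctmc(cs)
    if config is None:
        raise ValueError("an SSAConfig is required")
    if cs.params is None or cs.closure_name not in ("bernoulli", "split"):
        raise ValueError("batch_extinction supports the built-in closures only")
    X0 = _counts(X0)
    if omega is None:
        omega = cs.params.omega
    p = cs.params
    code = _kernels.CLOSURE_CODES[cs.closure_name]
    dummy_f = np.empty(1)
    dummy_i = np.empty(1, dtype=np.int64)
    out = []
    for rep in range(n):
        s32 = _seed32(config.seed, rep)
        _, _, _, _, _, face, face_time, _ = _kernels.ssa_core(
            code, p.m, p.c, p.k, p.e, float(omega),
            int(X0[0]), int(X0[1]),
            float(config.t_max), int(config.max_events), s32,
            False, dummy_f, dummy_i, dummy_i, dummy_i, True,
        )
        hit = face != 0 and face_time >= 0.0
        out.append(
            ExtinctionRecord(
                replicate=rep,
                seed=s32,
                extinction_time=float(face_time) if hit else None,
                boundary=_FACE_NAMES[face] if hit else "none",
                censored=not hit,
            )
        )
    return out
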