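"""Covariance geometry diagnostics.

Fluctuation geometry at the coexistence equilibrium is read directly off
the diffusion covariance ``a(K3)``: covariance ellipses (eigenvectors set
the axes, ``s * sqrt(eigenvalue)`` the semi-axes at sigma-level ``s``), the
signed cross-covariance ratio ``rho(K3) = a12 / sqrt(a11 a22)`` scanned
over the (m, k) plane with the Hopf threshold overlaid, and
survival-conditioned empirical covariance of simulated paths.  A negative
``a12`` tilts the major axis downward; the split (diagonal) closure gives
axis-aligned ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import ModelParams, Regime, classify_regime, equilibria
from .channels import ChannelSystem, build_channels, cross_cov_ratio
from .sde import DensityTrajectory, SDEConfig, ode_trajectory, simulate_absorbed, simulate_open_proxy

__all__ = [
    "EllipseGeometry",
    "covariance_ellipse",
    "ScanGrid",
    "rho_scan",
    "empirical_state_covariance",
    "RegimePair",
    "regime_comparison",
]


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned description of covariance contours at a state.

    ``semi_axes[level] = (major, minor)`` with semi-axes
    ``s * sqrt(eigenvalues)``; ``angle_deg`` is the orientation of the
    major axis versus the N-axis, mapped to (-90, 90] (0 for ties).
    """

    center: tuple[float, float]
    sigma_levels: tuple[float, ...]
    semi_axes: dict
    angle_deg: float
    eigenvalues: tuple[float, float]  # (major, minor)
    eigenvectors: np.ndarray  # columns, major first


def covariance_ellipse(a, center, sigma_levels=(1.0, 2.0)) -> EllipseGeometry:
    """Eigen-decompose a 2x2 PSD matrix into ellipse geometry."""
    a = np.asarray(a, dtype=float)
    w, v = np.linalg.eigh(a)
    if w[0] < -1e-12 * max(1.0, abs(w[1])):
        raise ValueError(f"matrix is not PSD (eigenvalues {w})")
    w = np.clip(w, 0.0, None)
    # eigh sorts ascending; put the major axis first
    lam = (float(w[1]), float(w[0]))
    vec = v[:, ::-1]
    if np.isclose(lam[0], lam[1]):
        angle = 0.0
    else:
        vx, vy = vec[0, 0], vec[1, 0]
        angle = float(np.degrees(np.arctan2(vy, vx)))
        if angle <= -90.0:
            angle += 180.0
        elif angle > 90.0:
            angle -= 180.0
    levels = tuple(float(s) for s in sigma_levels)
    semi = {s: (s * np.sqrt(lam[0]), s * np.sqrt(lam[1])) for s in levels}
    return EllipseGeometry(
        center=(float(center[0]), float(center[1])),
        sigma_levels=levels,
        semi_axes=semi,
        angle_deg=angle,
        eigenvalues=lam,
        eigenvectors=vec,
    )


@dataclass
class ScanGrid:
    """rho(K3) over an (m, k) grid with feasibility mask and Hopf overlay."""

    m_values: np.ndarray
    k_values: np.ndarray
    c: float
    e: float
    omega: float
    closure: str
    rho: np.ndarray  # (len(k), len(m)); NaN where infeasible
    feasible: np.ndarray  # boolean mask, same shape
    hopf_curve: np.ndarray  # k_H(m) on m_values, NaN where m <= c


def rho_scan(
    m_values,
    k_values,
    c: float,
    e: float = 1.0,
    omega: float = 500.0,
    closure: str = "effective",
) -> ScanGrid:
    """Evaluate the signed ratio rho at K3 over an (m, k) grid.

    Cells where the coexistence equilibrium is infeasible (``m <= c`` or
    ``k (m - c) <= c``) are masked; rho is Omega-invariant, so the choice
    of ``omega`` does not affect the values.
    """
    m_values = np.asarray(m_values, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if m_values.size == 0 or k_values.size == 0:
        raise ValueError("scan grids must be nonempty")
    if np.any(np.diff(m_values) <= 0) or np.any(np.diff(k_values) <= 0):
        raise ValueError("scan grids must be strictly increasing")

    rho = np.full((k_values.size, m_values.size), np.nan)
    feas = np.zeros_like(rho, dtype=bool)
    for j, m in enumerate(m_values):
        for i, k in enumerate(k_values):
            if not (m > c and k * (m - c) > c):
                continue
            params = ModelParams(m=m, c=c, k=k, e=e, omega=omega)
            k3 = equilibria(params).K3
            cs = build_channels(params, closure)
            rho[i, j] = cross_cov_ratio(cs, k3)
            feas[i, j] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        hopf = np.where(m_values > c, (m_values + c) / (m_values - c), np.nan)
    return ScanGrid(
        m_values=m_values,
        k_values=k_values,
        c=c,
        e=e,
        omega=omega,
        closure=closure,
        rho=rho,
        feasible=feas,
        hopf_curve=hopf,
    )


def empirical_state_covariance(
    traj: DensityTrajectory, burn_in: float = 0.0
):
    """Survival-conditioned sample covariance of (N_t, P_t) after burn-in.

    Uses grid times ``t >= burn_in`` and, for absorbed paths, strictly
    before ``tau``.  Returns (2x2 covariance, sample size).
    """
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    if traj.absorbed and traj.tau is not None and traj.tau <= burn_in:
        raise ValueError("trajectory absorbed before the end of the burn-in window")
    mask = traj.times >= burn_in
    if traj.absorbed and traj.tau is not None:
        mask &= traj.times < traj.tau
    pts = traj.states[mask]
    if pts.shape[0] < 10:
        raise ValueError(f"only {pts.shape[0]} usable points (need >= 10)")
    return np.cov(pts.T, bias=False), int(pts.shape[0])


@dataclass(frozen=True)
class RegimePair:
    """One stochastic path with its matched deterministic solution."""

    params: ModelParams
    regime: Regime
    sde: DensityTrajectory
    ode_times: np.ndarray
    ode_states: np.ndarray


def regime_comparison(
    params_list,
    x0_fn,
    sde_config: SDEConfig,
    ode_grid,
    closure: str = "bernoulli",
) -> list[RegimePair]:
    """Paired SDE/ODE runs across a list of parameter sets.

    ``x0_fn`` maps a ModelParams to the initial density (e.g. its K3);
    each pair is labeled by its Hopf regime.  The same seed is reused
    across parameter sets so bundles are reproducible.
    """
    ode_grid = np.asarray(ode_grid, dtype=float)
    out = []
    for params in params_list:
        x0 = x0_fn(params)
        cs = build_channels(params, closure)
        sim = (
            simulate_absorbed
            if sde_config.formulation == "absorbed"
            else simulate_open_proxy
        )
        traj = sim(cs, x0, sde_config)
        ode = ode_trajectory(params, x0, ode_grid)
        out.append(
            RegimePair(
                params=params,
                regime=classify_regime(params),
                sde=traj,
                ode_times=ode_grid,
                ode_states=ode,
            )
        )
    return out
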