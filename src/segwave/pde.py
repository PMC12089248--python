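"""Finite-volume solver for the continuum limit of the lattice model.

The system, for phenotype densities ``n_i(t, x)`` and pressure
``p = sum_i omega_i n_i``::

    dn_i/dt - mu_i d/dx( n_i dp/dx ) = alpha_i G(p) n_i

with zero-flux boundaries on ``[0, L]``.  Space is discretised with
cell-centred finite volumes and first-order upwind fluxes (edge velocity
``u = -mu_i dp/dx`` from central pressure differences, density taken from
the upwind cell), time with explicit Euler under a CFL bound.  Fluxes
telescope, so phenotypes without growth conserve mass to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .scenario import InvalidParameterError, ScenarioConfig, cell_centres, initial_densities

__all__ = [
    "FieldState",
    "pressure",
    "stable_dt",
    "pde_step",
    "run_pde",
    "PDEResult",
]

#: relative negativity tolerance: undershoots below ``-NEG_TOL_REL * scale``
#: abort the run, smaller ones are clipped to zero.
NEG_TOL_REL = 1e-12


def pressure(n: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Cellular pressure ``p_j = sum_i omega_i n_{i,j}``."""
    n = np.asarray(n, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if n.shape[0] != omega.size:
        raise InvalidParameterError(
            f"n has {n.shape[0]} phenotypes but omega has {omega.size} entries"
        )
    return omega @ n


@dataclass
class FieldState:
    """Continuum densities on a cell-centred grid at one instant."""

    n: np.ndarray  # (I, J) densities
    x: np.ndarray  # (J,) cell centres
    t: float
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else float(2 * self.x[0])

    @property
    def p(self) -> np.ndarray:
        return pressure(self.n, self.omega)

    def masses(self) -> np.ndarray:
        return self.n.sum(axis=1) * self.dx


def stable_dt(state: FieldState, config: ScenarioConfig) -> float:
    """Largest admissible explicit step: ``cfl dx^2 / (2 max(mu) max(p))``
    capped by the reaction sub-limit ``0.1 / (alpha_1 |G(0)|)``."""
    mu_max = float(config.phenotypes.mu.max())
    pmax = float(state.p.max())
    dt_adv = config.disc.cfl * state.dx**2 / (2.0 * mu_max * pmax + 1e-300)
    a = config.phenotypes.alpha
    g0 = abs(float(np.asarray(config.growth.G(0.0))))
    dt_react = 0.1 / (float(a.max()) * g0) if a.max() > 0 and g0 > 0 else np.inf
    return min(dt_adv, dt_react)


def pde_step(state: FieldState, config: ScenarioConfig, dt: float) -> FieldState:
    """One explicit upwind step of size ``dt`` (reference implementation).

    Raises if ``dt`` exceeds the stability bound or the state stops being
    finite.  The compiled kernel in :func:`run_pde` performs the same
    update.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    bound = stable_dt(state, config)
    if dt > bound * (1 + 1e-9):
        raise InvalidParameterError(
            f"dt={dt:.4g} exceeds the stability bound {bound:.4g}"
        )
    n = state.n
    I, J = n.shape
    dx = state.dx
    p = state.p
    if not np.all(np.isfinite(p)):
        raise FloatingPointError(f"non-finite pressure at t={state.t}")
    mu = config.phenotypes.mu
    alpha = config.phenotypes.alpha
    G = np.asarray(config.growth.G(p), dtype=float)
    dp = np.diff(p)  # p_{j+1} - p_j at interior edges
    new = np.empty_like(n)
    for i in range(I):
        u = -mu[i] * dp / dx
        nup = np.where(u > 0.0, n[i, :-1], n[i, 1:])
        F = np.zeros(J + 1)
        F[1:-1] = u * nup  # boundary edge fluxes stay zero
        new[i] = n[i] + dt / dx * (F[:-1] - F[1:])
        new[i] *= 1.0 + dt * alpha[i] * G
    scale = config.pbar / config.phenotypes.omega
    for i in range(I):
        if np.any(new[i] < -NEG_TOL_REL * scale[i]):
            raise FloatingPointError(
                f"density undershoot beyond tolerance for phenotype {i + 1} at t={state.t}"
            )
    np.clip(new, 0.0, None, out=new)
    return FieldState(n=new, x=state.x, t=state.t + dt, omega=state.omega)


@dataclass
class PDEResult:
    """Density time series of a finite-volume run."""

    times: np.ndarray  # (T,) including t = 0
    densities: np.ndarray  # (T, I, J)
    x: np.ndarray
    omega: np.ndarray

    def pressure(self) -> np.ndarray:
        return np.einsum("i,tij->tj", self.omega, self.densities)


def run_pde(config: ScenarioConfig) -> PDEResult:
    """Integrate the system to ``t_end``, emitting states at the configured
    output times (exact landing by truncating the adaptive step)."""
    dx = config.disc.dx_pde
    x = cell_centres(config.disc.L, dx)
    n = initial_densities(config, x)
    out_times = np.asarray(config.disc.output_times, dtype=float)
    I, J = n.shape
    densities = np.empty((out_times.size + 1, I, J))
    densities[0] = n
    omega = config.phenotypes.omega.astype(float)
    use_kernel = config.growth.name == "arctan"
    a = config.phenotypes.alpha
    g0 = abs(float(np.asarray(config.growth.G(0.0))))
    dt_react = 0.1 / (float(a.max()) * g0) if a.max() > 0 and g0 > 0 else np.inf
    neg_tol = NEG_TOL_REL * config.pbar / config.phenotypes.omega
    t = 0.0
    if use_kernel:
        work = n.copy()
        for k, t_target in enumerate(out_times):
            t, status = _kernels.pde_kernel(
                work,
                t,
                float(t_target),
                float(dx),
                config.phenotypes.mu.astype(float),
                a.astype(float),
                omega,
                config.pbar,
                float(config.disc.cfl),
                float(dt_react),
                neg_tol.astype(float),
            )
            if status != _kernels.STATUS_OK:
                raise FloatingPointError(
                    f"finite-volume update failed near t={t:.6g} (status {status})"
                )
            densities[k + 1] = work
    else:
        state = FieldState(n=n.copy(), x=x, t=0.0, omega=omega)
        for k, t_target in enumerate(out_times):
            while state.t < t_target - 1e-12 * (1 + abs(t_target)):
                dt = min(stable_dt(state, config), t_target - state.t)
                state = pde_step(state, config, dt)
            densities[k + 1] = state.n
    times = np.concatenate([[0.0], out_times])
    return PDEResult(times=times, densities=densities, x=x, omega=omega)
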