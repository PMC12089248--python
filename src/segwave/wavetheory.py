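"""Travelling-wave theory for the segregated invasion front.

In the wave frame ``z = x - c t`` the phenotypes occupy consecutive
intervals ``(z_{i-1}, z_i)`` with ``z_1 = 0`` and the pressure ``p(z)`` is
continuous, strictly decreasing, and piecewise linear ahead of the bulk:
on ``(z_{i-1}, z_i)`` for ``i >= 2`` it has slope ``-c / mu_i``, so at each
interface the one-sided slopes jump by the mobility ratio while the flux
``-mu_i p'`` stays equal to ``c`` (the kink conditions).  The interface
pressures are fixed by the conserved masses ``M_i`` of the non-growing
phenotypes::

    p(z_i) = sqrt( 2 c sum_{j > i} (omega_j / mu_j) M_j )

Behind the front (``z < 0``) the pressure solves the nonlinear ODE

    -c p' - mu_1 (p p')' = alpha_1 G(p) p,    p(-inf) = pbar,

integrated here from the unstable manifold of the ``p = pbar``
equilibrium until the kink slope ``p' = -c / mu_1`` is reached.  The wave
speed is the unique ``c`` at which the rear value ``p(0^-)`` meets the
front value ``p(0^+)``: the rear value decreases with ``c`` while the
front value grows like ``sqrt(c)``, so a sign change brackets the root
and bisection converges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .scenario import InvalidParameterError, ScenarioConfig

__all__ = [
    "NoWaveError",
    "WaveProfile",
    "ShootingResult",
    "front_pressure_p0",
    "interface_pressures",
    "interface_positions",
    "density_jump",
    "rear_profile",
    "solve_wave_speed",
    "predicted_speed_from_p0",
]


class NoWaveError(RuntimeError):
    """No segregated travelling front exists for the given parameters."""


def _check_masses(M: np.ndarray) -> np.ndarray:
    M = np.atleast_1d(np.asarray(M, dtype=float))
    if M.size < 1:
        raise InvalidParameterError("need masses M_2..M_I for at least I = 2 phenotypes")
    if np.any(M <= 0):
        raise InvalidParameterError(f"masses must be positive, got {M}")
    return M


def front_pressure_p0(c: float, M, omega, mu) -> float:
    """Pressure at the rear/front interface ``z_1 = 0``:
    ``p(0) = sqrt(2 c sum_{j=2}^I (omega_j / mu_j) M_j)``.

    ``M`` holds the masses of phenotypes ``2..I``; ``omega`` and ``mu`` the
    full parameter vectors (length ``I``).
    """
    if c <= 0:
        raise InvalidParameterError("wave speed c must be positive")
    M = _check_masses(M)
    omega = np.asarray(omega, dtype=float)
    mu = np.asarray(mu, dtype=float)
    S = float(np.sum(omega[1:] / mu[1:] * M))
    return float(np.sqrt(2.0 * c * S))


def interface_pressures(c: float, M, omega, mu) -> np.ndarray:
    """Pressures at the interfaces ``z_1, ..., z_{I-1}``:
    ``p(z_i) = sqrt(2 c sum_{j=i+1}^I (omega_j / mu_j) M_j)`` —
    a strictly decreasing sequence ending above ``p(z_I) = 0``.
    """
    if c <= 0:
        raise InvalidParameterError("wave speed c must be positive")
    M = _check_masses(M)
    omega = np.asarray(omega, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = omega[1:] / mu[1:] * M  # contributions of phenotypes 2..I
    tail = np.cumsum(w[::-1])[::-1]  # tail[i] = sum_{j>=i+2} + own term
    return np.sqrt(2.0 * c * tail)


def interface_positions(c: float, M, omega, mu) -> np.ndarray:
    """Interface points ``z_2 < ... < z_I`` (with ``z_1 = 0`` implicit).

    Interior widths follow from the linear pressure segments,
    ``z_i - z_{i-1} = (mu_i / c)(p(z_{i-1}) - p(z_i))``; the leading
    segment has ``z_I - z_{I-1} = sqrt(2 omega_I mu_I M_I / c)``.
    """
    M = _check_masses(M)
    omega = np.asarray(omega, dtype=float)
    mu = np.asarray(mu, dtype=float)
    I = omega.size
    pz = interface_pressures(c, M, omega, mu)  # p(z_1) .. p(z_{I-1})
    z = np.empty(I - 1)
    prev = 0.0
    for i in range(2, I):  # z_2 .. z_{I-1}
        prev = prev + mu[i - 1] / c * (pz[i - 2] - pz[i - 1])
        z[i - 2] = prev
    z[I - 2] = prev + np.sqrt(2.0 * omega[I - 1] * mu[I - 1] * M[-1] / c)
    return z


def density_jump(omega_i: float, omega_ip1: float, n_left: float) -> float:
    """Density just right of an interface from the value just left of it.

    Pressure continuity forces ``n_{i+1}(z_i^+) = (omega_i / omega_{i+1})
    n_i(z_i^-)``: equal weights give a continuous density, a heavier
    phenotype ahead gives a drop, a lighter one a rise.
    """
    if omega_i <= 0 or omega_ip1 <= 0:
        raise InvalidParameterError("pressure weights must be positive")
    return omega_i / omega_ip1 * n_left


@dataclass
class ShootingResult:
    """One rear-profile integration at a candidate speed ``c``."""

    c: float
    p_left0: float  # p(0^-) where the rear reaches the kink slope
    p_right0: float  # p(0^+) from the mass relation (NaN if masses unknown)
    residual: float  # p_left0 - p_right0 (NaN if masses unknown)
    z: np.ndarray  # rear samples, z <= 0
    p: np.ndarray
    matched: bool = True


def rear_profile(
    c: float,
    config: ScenarioConfig,
    masses=None,
    p_stop: float | None = None,
    n_samples: int = 400,
) -> ShootingResult:
    """Integrate the rear pressure ODE at speed ``c`` down from ``pbar``.

    Starts on the unstable manifold of the saddle at ``p = pbar`` (offset
    ``1e-6 pbar`` along the eigenvector of the positive eigenvalue
    ``lambda_+`` of ``mu_1 pbar lam^2 + c lam + alpha_1 G'(pbar) pbar = 0``)
    and integrates until the kink slope ``p' = -c / mu_1`` is reached;
    the pressure there is ``p(0^-)``.

    ``p_stop`` is a pressure floor: if ``p`` falls below it before the
    slope event fires, the run is declared unmatched — with no floor given
    a tiny default is used and :class:`NoWaveError` is raised.  Because
    ``p`` decreases monotonically, an unmatched run at floor
    ``p_stop = p(0^+)`` proves the residual is negative, which is how
    :func:`solve_wave_speed` uses it.
    """
    if c <= 0:
        raise InvalidParameterError("wave speed c must be positive")
    phen = config.phenotypes
    pbar = config.pbar
    mu1 = float(phen.mu[0])
    alpha1 = float(phen.alpha[0])
    if alpha1 <= 0:
        raise NoWaveError(
            "alpha_1 must be positive: without growth of phenotype 1 the rear "
            "pressure stays at pbar and no front can form"
        )
    G = config.growth.G
    dG_pbar = float(np.asarray(config.growth.dG(pbar)))
    if not dG_pbar < 0:
        raise NoWaveError("growth law must be strictly decreasing at pbar")
    disc = c * c - 4.0 * mu1 * pbar * alpha1 * dG_pbar * pbar
    lam_plus = (-c + np.sqrt(disc)) / (2.0 * mu1 * pbar)
    p0 = pbar * (1.0 - 1e-6)
    q0 = lam_plus * (p0 - pbar)
    raise_on_miss = p_stop is None
    if p_stop is None:
        p_stop = 1e-9 * pbar
    if p0 <= p_stop:
        # already below the floor: trivially unmatched
        p_right0 = residual = np.nan
        if masses is not None:
            p_right0 = front_pressure_p0(c, masses, phen.omega, phen.mu)
            residual = -p_right0
        if raise_on_miss:
            raise NoWaveError(f"pressure floor {p_stop:.6g} is at or above pbar")
        return ShootingResult(
            c=c, p_left0=np.nan, p_right0=p_right0, residual=residual,
            z=np.array([0.0]), p=np.array([p0]), matched=False,
        )

    def rhs(z, y):
        p, q = y
        return [q, (-c * q - alpha1 * float(np.asarray(G(p))) * p - mu1 * q * q) / (mu1 * p)]

    def slope_event(z, y):
        return y[1] + c / mu1

    slope_event.terminal = True
    slope_event.direction = -1

    def floor_event(z, y):
        return y[0] - p_stop

    floor_event.terminal = True
    floor_event.direction = -1

    # the rear length scale is ~ log(pbar/offset)/lambda_+ plus an O(1) tail
    z_span = 50.0 * max(1.0, np.log(1e6) / max(lam_plus, 1e-12))
    sol = solve_ivp(
        rhs,
        [0.0, z_span],
        [p0, q0],
        events=[slope_event, floor_event],
        rtol=1e-9,
        atol=[1e-9 * pbar, 1e-9 * max(c / mu1, 1.0)],
        dense_output=True,
    )
    matched = sol.t_events[0].size > 0
    if matched:
        z_end = sol.t_events[0][0]
        p_left0 = float(sol.y_events[0][0][0])
    else:
        if raise_on_miss:
            raise NoWaveError(
                f"rear profile never reaches the kink slope -c/mu_1 at c={c:.6g}; "
                "no matching front exists at this speed"
            )
        z_end = sol.t[-1]
        p_left0 = np.nan
    zs = np.linspace(0.0, z_end, n_samples)
    ps = sol.sol(zs)[0] if sol.sol is not None else np.interp(zs, sol.t, sol.y[0])
    p_right0 = np.nan
    residual = np.nan
    if masses is not None:
        p_right0 = front_pressure_p0(c, masses, phen.omega, phen.mu)
        residual = p_left0 - p_right0 if matched else -p_right0
    return ShootingResult(
        c=c,
        p_left0=p_left0,
        p_right0=p_right0,
        residual=residual,
        z=zs - z_end,  # anchor the matching point at z = 0
        p=ps,
        matched=matched,
    )


@dataclass
class WaveProfile:
    """Assembled travelling-wave solution."""

    c: float
    z: np.ndarray  # interfaces z_1 = 0, z_2, ..., z_I
    pz: np.ndarray  # p(z_1), ..., p(z_{I-1}) (p(z_I) = 0)
    M: np.ndarray  # masses of phenotypes 2..I
    omega: np.ndarray
    mu: np.ndarray
    pbar: float
    rear_z: np.ndarray  # samples of the rear profile, z <= 0
    rear_p: np.ndarray

    def pressure(self, z) -> np.ndarray:
        """Evaluate ``p(z)`` piecewise: rear samples for ``z < 0``, linear
        segments with slope ``-c/mu_i`` on ``(z_{i-1}, z_i)``, zero beyond."""
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        rear = z < 0
        out[rear] = np.interp(z[rear], self.rear_z, self.rear_p, left=self.pbar)
        pz_ext = np.append(self.pz, 0.0)  # p at z_1..z_I
        for i in range(1, self.z.size):  # segment (z_{i-1}, z_i) -> phenotype i+1
            seg = (z >= self.z[i - 1]) & (z < self.z[i])
            out[seg] = pz_ext[i] + self.c / self.mu[i] * (self.z[i] - z[seg])
        return out

    def density(self, i: int, z) -> np.ndarray:
        """Density of phenotype ``i`` (1-based): ``n_i = p / omega_i`` on its
        own segment, zero elsewhere."""
        z = np.asarray(z, dtype=float)
        p = self.pressure(z)
        if i == 1:
            # phenotype 1 occupies z < z_1 = 0
            mask = z < 0
        else:
            mask = (z >= self.z[i - 2]) & (z < self.z[i - 1])
        out = np.zeros_like(z)
        out[mask] = p[mask] / self.omega[i - 1]
        return out

    def slope_left(self, i: int) -> float:
        """One-sided pressure slope ``p'(z_i^-)`` at interface ``i`` (1-based)."""
        return -self.c / self.mu[i - 1]

    def slope_right(self, i: int) -> float:
        """One-sided pressure slope ``p'(z_i^+)``."""
        return -self.c / self.mu[i]


def solve_wave_speed(
    config: ScenarioConfig,
    M,
    bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-12,
    max_expand: int = 60,
) -> WaveProfile:
    """Find the unique wave speed by bisecting the matching residual
    ``p(0^-) - p(0^+)`` and assemble the full :class:`WaveProfile`.

    The initial bracket is expanded geometrically until the residual
    changes sign; :class:`NoWaveError` is raised if it never does (e.g.
    when the segregation assumptions fail).
    """
    phen = config.phenotypes
    if not phen.segregation_assumptions_hold():
        raise NoWaveError(
            "travelling-wave theory requires mu strictly increasing, "
            "alpha_1 > 0 and alpha_i = 0 for i >= 2"
        )
    M = _check_masses(M)
    if M.size != phen.I - 1:
        raise InvalidParameterError(
            f"need I-1 = {phen.I - 1} masses (phenotypes 2..I), got {M.size}"
        )

    def residual(c: float) -> float:
        front = front_pressure_p0(c, M, phen.omega, phen.mu)
        res = rear_profile(c, config, masses=M, p_stop=0.999 * front)
        return res.residual

    lo, hi = bracket
    r_lo = residual(lo)
    r_hi = residual(hi)
    n = 0
    while r_lo < 0 and n < max_expand:  # root below lo
        lo /= 4.0
        r_lo = residual(lo)
        n += 1
    while r_hi > 0 and n < max_expand:  # root above hi
        hi *= 4.0
        r_hi = residual(hi)
        n += 1
    if not (r_lo > 0 >= r_hi):
        raise NoWaveError(
            f"no sign change of the matching residual in c ∈ [{lo:.3g}, {hi:.3g}]"
        )
    c = float(brentq(residual, lo, hi, xtol=tol))
    rear = rear_profile(c, config, masses=M)
    pz = interface_pressures(c, M, phen.omega, phen.mu)
    z_rest = interface_positions(c, M, phen.omega, phen.mu)
    z = np.concatenate([[0.0], z_rest])
    return WaveProfile(
        c=c,
        z=z,
        pz=pz,
        M=M,
        omega=phen.omega.copy(),
        mu=phen.mu.copy(),
        pbar=config.pbar,
        rear_z=rear.z,
        rear_p=rear.p,
    )


def predicted_speed_from_p0(p0: float, M, omega, mu) -> float:
    """Wave speed from a measured interface pressure:
    ``c = p(0)^2 / (2 sum_{j=2}^I (omega_j / mu_j) M_j)`` — the exact
    algebraic inverse of :func:`front_pressure_p0`."""
    if p0 < 0:
        raise InvalidParameterError("p0 must be non-negative")
    M = _check_masses(M)
    omega = np.asarray(omega, dtype=float)
    mu = np.asarray(mu, dtype=float)
    S = float(np.sum(omega[1:] / mu[1:] * M))
    if S <= 0:
        raise InvalidParameterError("mass-weighted sum must be positive")
    return float(p0 * p0 / (2.0 * S))
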