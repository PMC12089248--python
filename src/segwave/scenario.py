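"""Model parameters, growth law, lattice/continuum scaling, and initial conditions.

The model describes a cell population subdivided into ``I >= 2`` discrete
phenotypes on a one-dimensional domain.  Each phenotype ``i`` carries

* a pressure weight ``omega_i`` (its contribution per unit density to the
  cellular pressure ``p = sum_i omega_i n_i``),
* a mobility ``mu_i`` (continuum drift rate down the pressure gradient),
* a growth time-scale factor ``alpha_i`` multiplying a shared net-growth
  law ``G(p)`` with ``G(pbar) = 0`` at the homeostatic pressure ``pbar``.

The lattice counterpart of ``mu_i`` is the dimensionless pressure
sensitivity ``gamma_i = 2 tau pbar mu_i / dx**2``; keeping ``gamma_i``
fixed while ``dx, tau -> 0`` is the scaling under which the stochastic
lattice model converges to the continuum PDE system.

Everything downstream (IBM, PDE solver, wave theory, experiment runner)
consumes the :class:`ScenarioConfig` assembled here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "GrowthLaw",
    "PhenotypeParams",
    "DiscretizationParams",
    "InitialCondition",
    "ScenarioConfig",
    "make_growth_law",
    "gamma_from_mu",
    "mu_from_gamma",
    "baseline_scenario",
    "initial_densities",
    "cell_centres",
    "SCENARIO_REGISTRY",
    "registered_scenarios",
    "get_scenario",
]


class InvalidParameterError(ValueError):
    """A model or discretization parameter violates its constraints."""


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthLaw:
    """Net-growth factor ``G(p)`` shared by all phenotypes.

    ``G`` must be strictly decreasing with ``G(pbar) = 0``: cells divide
    below the homeostatic pressure and die above it.  ``dG`` is the
    derivative of ``G`` with respect to pressure (used by the travelling
    wave solver to linearise about ``p = pbar``).
    """

    pbar: float
    G: Callable[[np.ndarray | float], np.ndarray | float]
    dG: Callable[[np.ndarray | float], np.ndarray | float]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.pbar > 0:
            raise InvalidParameterError(f"pbar must be positive, got {self.pbar}")


def make_growth_law(pbar: float, kind: str = "arctan") -> GrowthLaw:
    """Return the built-in growth law ``G(p) = arctan((1/10)(1 - p/pbar))``.

    The arctan saturates the per-capita rate at high and low pressure while
    keeping ``G`` smooth, strictly decreasing, and zero exactly at ``pbar``.
    """
    if not (isinstance(pbar, (int, float)) and math.isfinite(pbar) and pbar > 0):
        raise InvalidParameterError(f"pbar must be a positive finite number, got {pbar!r}")
    if kind != "arctan":
        raise InvalidParameterError(f"unknown growth-law kind {kind!r}")
    pbar = float(pbar)

    def G(p):
        return np.arctan(0.1 * (1.0 - np.asarray(p, dtype=float) / pbar))

    def dG(p):
        u = 0.1 * (1.0 - np.asarray(p, dtype=float) / pbar)
        return (-0.1 / pbar) / (1.0 + u * u)

    return GrowthLaw(pbar=pbar, G=G, dG=dG, name="arctan")


def growth_law_with_fd_derivative(
    pbar: float, G: Callable, name: str = "custom"
) -> GrowthLaw:
    """Wrap a user-supplied ``G`` with a central finite-difference derivative.

    The step is ``1e-6 * pbar``, small against the pressure scale but large
    against double-precision rounding of ``G`` values of order one.
    """
    h = 1e-6 * pbar

    def dG(p):
        return (np.asarray(G(np.asarray(p) + h)) - np.asarray(G(np.asarray(p) - h))) / (2 * h)

    return GrowthLaw(pbar=pbar, G=G, dG=dG, name=name)


# ---------------------------------------------------------------------------
# lattice <-> continuum scaling
# ---------------------------------------------------------------------------


def gamma_from_mu(mu, tau: float, dx: float, pbar: float):
    """Lattice pressure sensitivity ``gamma = 2 tau pbar mu / dx**2``.

    This is the unique choice for which the biased random walk converges to
    the advection term ``-mu d/dx(n dp/dx)`` as ``dx, tau -> 0``.  Values
    ``gamma >= 1`` make single-step movement probabilities potentially
    leave ``[0, 1)`` and trigger a warning here (and a hard error at
    simulation time if an actual probability is invalid).
    """
    mu = np.asarray(mu, dtype=float)
    if tau <= 0 or dx <= 0 or pbar <= 0:
        raise InvalidParameterError("tau, dx and pbar must be positive")
    if np.any(mu < 0):
        raise InvalidParameterError("mobility mu must be non-negative")
    gamma = 2.0 * tau * pbar * mu / dx**2
    if np.any(gamma >= 1.0):
        warnings.warn(
            f"gamma = {gamma} has entries >= 1: movement probabilities may leave [0,1)",
            stacklevel=2,
        )
    return gamma if gamma.ndim else float(gamma)


def mu_from_gamma(gamma, tau: float, dx: float, pbar: float):
    """Exact algebraic inverse of :func:`gamma_from_mu`."""
    gamma = np.asarray(gamma, dtype=float)
    if tau <= 0 or dx <= 0 or pbar <= 0:
        raise InvalidParameterError("tau, dx and pbar must be positive")
    mu = gamma * dx**2 / (2.0 * tau * pbar)
    return mu if mu.ndim else float(mu)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeParams:
    """Per-phenotype weights, mobilities and growth factors.

    ``gamma`` is derived (lattice sensitivity); when absent it is filled
    from ``mu`` and the discretization via :func:`gamma_from_mu`.
    """

    omega: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        I = self.omega.size
        if I < 2:
            raise InvalidParameterError(f"need at least 2 phenotypes, got I={I}")
        for name in ("mu", "alpha"):
            if getattr(self, name).size != I:
                raise InvalidParameterError(f"{name} must have length I={I}")
        if np.any(self.omega <= 0):
            raise InvalidParameterError(f"omega must be positive, got {self.omega}")
        if np.any(self.mu <= 0):
            raise InvalidParameterError(f"mu must be positive, got {self.mu}")
        if np.any(self.alpha < 0):
            raise InvalidParameterError(f"alpha must be non-negative, got {self.alpha}")

    @property
    def I(self) -> int:
        return self.omega.size

    def segregation_assumptions_hold(self) -> bool:
        """True when the travelling-wave assumptions hold: ``mu`` strictly
        increasing, ``alpha_1 > 0`` and ``alpha_i = 0`` for ``i >= 2``."""
        return bool(
            np.all(np.diff(self.mu) > 0)
            and self.alpha[0] > 0
            and np.all(self.alpha[1:] == 0)
        )


@dataclass
class DiscretizationParams:
    """Space/time steps, domain length and reporting horizon."""

    dx: float = 0.1
    tau: float = 1e-4
    L: float = 150.0
    t_end: float = 150.0
    output_times: np.ndarray | None = None
    dx_pde: float | None = None  # PDE grid step; defaults to dx
    cfl: float = 0.9

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.tau <= 0 or self.L <= 0:
            raise InvalidParameterError("dx, tau and L must be positive")
        n_sites = self.L / self.dx
        if abs(n_sites - round(n_sites)) > 1e-9 * max(1.0, n_sites):
            warnings.warn(
                f"L/dx = {n_sites} is not an integer; rounding to {round(n_sites)} sites",
                stacklevel=2,
            )
        if self.output_times is None:
            step = max(1.0, self.t_end / 150.0)
            self.output_times = np.arange(step, self.t_end + 1e-9, step)
        self.output_times = np.asarray(self.output_times, dtype=float)
        if np.any(self.output_times <= 0) or np.any(self.output_times > self.t_end + 1e-9):
            raise InvalidParameterError("output_times must lie in (0, t_end]")
        if np.any(np.diff(self.output_times) <= 0):
            raise InvalidParameterError("output_times must be strictly increasing")
        if self.dx_pde is None:
            self.dx_pde = self.dx

    @property
    def n_sites(self) -> int:
        return int(round(self.L / self.dx))


@dataclass
class InitialCondition:
    """Segmented-Gaussian initial densities.

    Phenotype ``i`` starts as ``A_i * exp(-B (x - x_i0)**2)`` on its own
    window ``[seg_left_i, seg_right_i)`` (windows of width 10 starting at
    0, the last one extended to ``L``), zero elsewhere.  Disjoint windows
    give a spatially segregated start.
    """

    A: np.ndarray
    B: float = 6e-2
    seg_left: np.ndarray | None = None
    seg_right: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if np.any(self.A <= 0):
            raise InvalidParameterError(f"amplitudes A must be positive, got {self.A}")
        if self.B <= 0:
            raise InvalidParameterError("Gaussian width parameter B must be positive")
        if self.seg_left is not None:
            self.seg_left = np.asarray(self.seg_left, dtype=float)
        if self.seg_right is not None:
            self.seg_right = np.asarray(self.seg_right, dtype=float)

    def segments(self, L: float) -> tuple[np.ndarray, np.ndarray]:
        I = self.A.size
        if self.seg_left is not None and self.seg_right is not None:
            left, right = self.seg_left, self.seg_right
        else:
            left = 10.0 * np.arange(I)
            right = np.append(10.0 * (np.arange(1, I)), L)
        if np.any(right <= left) or np.any(left[1:] < right[:-1]):
            raise InvalidParameterError("segments must be disjoint and ordered")
        return left, right


@dataclass
class ScenarioConfig:
    """Everything a run needs: phenotypes, growth law, grid, and ICs."""

    phenotypes: PhenotypeParams
    growth: GrowthLaw
    disc: DiscretizationParams
    ic: InitialCondition
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.ic.A.size != self.phenotypes.I:
            raise InvalidParameterError("one amplitude A_i per phenotype is required")
        if self.phenotypes.gamma is None:
            self.phenotypes.gamma = gamma_from_mu(
                self.phenotypes.mu, self.disc.tau, self.disc.dx, self.growth.pbar
            )
        if not self.phenotypes.segregation_assumptions_hold():
            warnings.warn(
                "parameters violate the segregation assumptions "
                "(mu strictly increasing, alpha_1 > 0, alpha_i = 0 for i >= 2); "
                "simulation is allowed but the travelling-wave theory does not apply",
                stacklevel=2,
            )

    @property
    def I(self) -> int:
        return self.phenotypes.I

    @property
    def pbar(self) -> float:
        return self.growth.pbar

    def with_discretization(self, **kwargs) -> "ScenarioConfig":
        """Copy of the config with some discretization fields replaced.

        ``gamma`` is re-derived from ``mu`` for the new lattice steps.
        """
        if "dx" in kwargs and "dx_pde" not in kwargs:
            kwargs["dx_pde"] = kwargs["dx"]
        if "t_end" in kwargs and "output_times" not in kwargs:
            kwargs["output_times"] = None  # regenerate for the new horizon
        disc = replace(self.disc, **kwargs)
        phen = PhenotypeParams(
            omega=self.phenotypes.omega.copy(),
            mu=self.phenotypes.mu.copy(),
            alpha=self.phenotypes.alpha.copy(),
            gamma=None,
        )
        return ScenarioConfig(
            phenotypes=phen, growth=self.growth, disc=disc, ic=self.ic, name=self.name
        )


# ---------------------------------------------------------------------------
# baseline scenarios
# ---------------------------------------------------------------------------

_OMEGA_VARIANTS = {
    (3, "increasing"): (1.0, 2.0, 3.0),
    (3, "equal"): (2.0, 2.0, 2.0),
    (3, "decreasing"): (3.0, 2.0, 1.0),
    (4, "increasing"): (1.0, 2.0, 3.0, 4.0),
    (4, "equal"): (2.0, 2.0, 2.0, 2.0),
    (4, "decreasing"): (4.0, 3.0, 2.0, 1.0),
}

PBAR_BASELINE = 4e4


def baseline_scenario(
    I: int,
    omega_variant: str = "increasing",
    A: Sequence[float] | None = None,
    name: str | None = None,
) -> ScenarioConfig:
    """The baseline parameter sets for ``I = 3`` or ``I = 4`` phenotypes.

    Phenotype 1 is the fast-dividing, least mobile one (``alpha_1 = 10``,
    all other ``alpha_i = 0``); mobilities increase linearly,
    ``mu = (1, 2, 3[, 4]) x 1e-4``.  The pressure weights depend on the
    variant: ``increasing`` (1,2,3[,4]), ``equal`` (2,2,2[,2]) or
    ``decreasing`` (3,2,1)/(4,3,2,1).  Homeostatic pressure
    ``pbar = 4e4``; lattice ``dx = 0.1``, ``tau = 1e-4`` on ``[0, 150]``.

    Amplitudes default to ``A_i = pbar / omega_i`` so every segment's peak
    pressure equals ``pbar``, making the initial pressure profile identical
    across the omega variants; pass ``A`` to override.
    """
    if I not in (3, 4):
        raise InvalidParameterError(f"baseline scenarios are defined for I in {{3, 4}}, got I={I}")
    if (I, omega_variant) not in _OMEGA_VARIANTS:
        raise InvalidParameterError(
            f"unknown omega variant {omega_variant!r}; choose from "
            "'increasing', 'equal', 'decreasing'"
        )
    omega = np.array(_OMEGA_VARIANTS[(I, omega_variant)])
    mu = np.arange(1, I + 1) * 1e-4
    alpha = np.zeros(I)
    alpha[0] = 10.0
    pbar = PBAR_BASELINE
    if A is None:
        A = pbar / omega
    phen = PhenotypeParams(omega=omega, mu=mu, alpha=alpha)
    disc = DiscretizationParams(dx=0.1, tau=1e-4, L=150.0, t_end=150.0)
    ic = InitialCondition(A=np.asarray(A, dtype=float), B=6e-2)
    if name is None:
        name = f"baseline_I{I}_{omega_variant}"
    return ScenarioConfig(
        phenotypes=phen, growth=make_growth_law(pbar), disc=disc, ic=ic, name=name
    )


#: Named scenarios mirroring the published figures.
SCENARIO_REGISTRY: dict[str, Callable[[], ScenarioConfig]] = {
    "fig3": lambda: baseline_scenario(3, "increasing", name="fig3"),
    "fig4": lambda: baseline_scenario(4, "increasing", name="fig4"),
    "fig6a": lambda: baseline_scenario(3, "increasing", name="fig6a"),
    "fig6b": lambda: baseline_scenario(3, "equal", name="fig6b"),
    "fig6c": lambda: baseline_scenario(3, "decreasing", name="fig6c"),
    "fig7a": lambda: baseline_scenario(4, "increasing", name="fig7a"),
    "fig7b": lambda: baseline_scenario(4, "equal", name="fig7b"),
    "fig7c": lambda: baseline_scenario(4, "decreasing", name="fig7c"),
}


def registered_scenarios() -> list[str]:
    return sorted(SCENARIO_REGISTRY)


def get_scenario(name: str) -> ScenarioConfig:
    try:
        factory = SCENARIO_REGISTRY[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; registered scenarios: {registered_scenarios()}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# grids and initial densities
# ---------------------------------------------------------------------------


def cell_centres(L: float, dx: float) -> np.ndarray:
    """Cell/site centres ``x_j = (j + 1/2) dx`` covering ``[0, L)``.

    Both the lattice model and the finite-volume solver use this grid, so
    the two can be compared pointwise without interpolation.
    """
    J = int(round(L / dx))
    return (np.arange(J) + 0.5) * dx


def initial_densities(config: ScenarioConfig, grid: np.ndarray) -> np.ndarray:
    """Per-phenotype initial densities ``n_i(0, x)`` on ``grid``.

    Raises :class:`InvalidParameterError` if the resulting initial
    pressure exceeds ``pbar`` anywhere.
    """
    grid = np.asarray(grid, dtype=float)
    I = config.I
    A = config.ic.A
    B = config.ic.B
    left, right = config.ic.segments(config.disc.L)
    n0 = np.zeros((I, grid.size))
    for i in range(I):
        mask = (grid >= left[i]) & (grid < right[i])
        n0[i, mask] = A[i] * np.exp(-B * (grid[mask] - left[i]) ** 2)
    p0 = config.phenotypes.omega @ n0
    pbar = config.pbar
    if np.any(p0 > pbar * (1 + 1e-12)):
        raise InvalidParameterError(
            f"initial pressure exceeds pbar (max {p0.max():.6g} > {pbar:.6g}); "
            "reduce the amplitudes A_i"
        )
    return n0
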