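"""Stochastic individual-based model: a branching biased random walk.

Cells of phenotype ``i`` sit on a 1-D lattice of sites of width ``dx``.
In one time step ``tau`` a cell at site ``j`` may

* divide with probability ``tau (alpha_i G(p_j))_+`` or die with
  probability ``tau (alpha_i G(p_j))_-`` — pressure-regulated growth,
* hop left/right with probabilities
  ``gamma_i (p_j - p_{j -/+ 1})_+ / (2 pbar)`` — movement down the
  pressure gradient, biased by the phenotype's sensitivity ``gamma_i``.

Movement and division are independent within a step; probabilities are
all evaluated from the frozen start-of-step state, daughters are placed
at the mover's destination, and moves off the domain are aborted
(zero-flux walls).  Per site the (left, right, stay) split is drawn as a
chained binomial — an exact multinomial split, distributionally identical
to per-cell uniform draws but much faster.

:func:`run_ibm` drives a compiled kernel for the built-in growth law and
falls back to the pure-numpy :func:`step` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scenario import InvalidParameterError, ScenarioConfig, cell_centres, initial_densities

__all__ = [
    "ProbabilityError",
    "LatticeState",
    "EventProbabilities",
    "IBMResult",
    "initial_counts",
    "event_probabilities",
    "step",
    "run_ibm",
]


class ProbabilityError(RuntimeError):
    """A single-step event probability left its admissible range."""


@dataclass
class LatticeState:
    """Integer cell counts per phenotype and lattice site."""

    N: np.ndarray  # (I, J) int64 counts
    dx: float
    tau: float
    k: int = 0  # time-step index

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N)
        if self.N.ndim != 2:
            raise InvalidParameterError("N must be a (phenotype, site) array")
        if np.any(self.N < 0):
            raise InvalidParameterError("cell counts must be non-negative")
        self.N = self.N.astype(np.int64)

    @property
    def t(self) -> float:
        return self.k * self.tau

    def densities(self) -> np.ndarray:
        return self.N / self.dx

    def pressure(self, omega: np.ndarray) -> np.ndarray:
        return np.asarray(omega, dtype=float) @ self.densities()


@dataclass
class EventProbabilities:
    """Per-site, per-phenotype single-step event probabilities."""

    p_div: np.ndarray
    p_die: np.ndarray
    p_left: np.ndarray
    p_right: np.ndarray


def initial_counts(config: ScenarioConfig, rounding: str = "round") -> LatticeState:
    """Lattice counts ``N = round(n_i(0, x_j) dx)`` from the config's ICs.

    ``rounding`` may be ``"round"`` (default) or ``"floor"``.
    """
    x = cell_centres(config.disc.L, config.disc.dx)
    n0 = initial_densities(config, x)
    raw = n0 * config.disc.dx
    if rounding == "round":
        N = np.round(raw)
    elif rounding == "floor":
        N = np.floor(raw)
    else:
        raise InvalidParameterError(f"unknown rounding {rounding!r}")
    return LatticeState(N=N.astype(np.int64), dx=config.disc.dx, tau=config.disc.tau)


def event_probabilities(state: LatticeState, config: ScenarioConfig) -> EventProbabilities:
    """Division, death and movement probabilities for the current state.

    Raises :class:`ProbabilityError` naming the first offending site if any
    probability leaves [0, 1] or a site's move probabilities sum to >= 1.
    """
    phen = config.phenotypes
    pbar = config.pbar
    tau = state.tau
    p = state.pressure(phen.omega)  # (J,)
    G = np.asarray(config.growth.G(p), dtype=float)  # (J,)
    aG = phen.alpha[:, None] * G[None, :]  # (I, J)
    p_div = tau * np.maximum(aG, 0.0)
    p_die = tau * np.maximum(-aG, 0.0)
    # out-of-domain neighbours contribute zero move probability
    dl = np.zeros_like(p)
    dr = np.zeros_like(p)
    dl[1:] = p[1:] - p[:-1]
    dr[:-1] = p[:-1] - p[1:]
    gam = phen.gamma[:, None]
    p_left = gam * np.maximum(dl, 0.0)[None, :] / (2.0 * pbar)
    p_right = gam * np.maximum(dr, 0.0)[None, :] / (2.0 * pbar)

    bad = p_div + p_die > 1.0
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ProbabilityError(
            f"division+death probability > 1 for phenotype {i + 1} at site {j} "
            f"(p_div={p_div[i, j]:.3g}, p_die={p_die[i, j]:.3g}); reduce tau"
        )
    bad = p_left + p_right >= 1.0
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ProbabilityError(
            f"movement probabilities sum to >= 1 for phenotype {i + 1} at site {j} "
            f"(p_left={p_left[i, j]:.3g}, p_right={p_right[i, j]:.3g}); "
            "reduce tau or dx (gamma too large)"
        )
    return EventProbabilities(p_div=p_div, p_die=p_die, p_left=p_left, p_right=p_right)


def step(
    state: LatticeState, config: ScenarioConfig, rng: np.random.Generator
) -> LatticeState:
    """One synchronous update of the lattice state (reference implementation).

    Distributionally identical to the compiled kernel; used for small
    states, custom growth laws, and as the behavioural reference in tests.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("an explicitly seeded numpy Generator is required")
    probs = event_probabilities(state, config)
    I, J = state.N.shape
    N = state.N
    pl, pr = probs.p_left, probs.p_right
    # multinomial split into (left, right, stay) movers
    nl = rng.binomial(N, pl)
    rem = N - nl
    with np.errstate(divide="ignore", invalid="ignore"):
        pr_cond = np.where(pl < 1.0, pr / (1.0 - pl), 0.0)
    nr = rng.binomial(rem, pr_cond)
    ns = rem - nr
    # division/death with the origin site's pressure, applied per mover group
    delta_l = rng.binomial(nl, probs.p_div) - rng.binomial(nl, probs.p_die)
    delta_s = rng.binomial(ns, probs.p_div) - rng.binomial(ns, probs.p_die)
    delta_r = rng.binomial(nr, probs.p_div) - rng.binomial(nr, probs.p_die)
    new = np.zeros_like(N)
    # stayers
    new += ns + delta_s
    # left movers: site 0 moves are aborted (cell stays)
    left = nl + delta_l
    new[:, :-1] += left[:, 1:]
    new[:, 0] += left[:, 0]
    # right movers: site J-1 moves are aborted
    right = nr + delta_r
    new[:, 1:] += right[:, :-1]
    new[:, -1] += right[:, -1]
    return LatticeState(N=new, dx=state.dx, tau=state.tau, k=state.k + 1)


@dataclass
class IBMResult:
    """Per-replicate and replicate-averaged density time series."""

    times: np.ndarray  # (T,) including t = 0
    densities: np.ndarray  # (reps, T, I, J)
    x: np.ndarray  # (J,) site centres
    omega: np.ndarray
    seeds: np.ndarray = field(default=None)

    @property
    def mean_densities(self) -> np.ndarray:
        return self.densities.mean(axis=0)

    def pressure(self, rep: int | None = None) -> np.ndarray:
        """Pressure series (T, J); replicate-averaged when ``rep`` is None."""
        n = self.mean_densities if rep is None else self.densities[rep]
        return np.einsum("i,tij->tj", self.omega, n)


def _record_steps(config: ScenarioConfig) -> np.ndarray:
    tau = config.disc.tau
    steps = np.round(np.asarray(config.disc.output_times) / tau).astype(np.int64)
    if np.any(np.abs(steps * tau - config.disc.output_times) > 1e-9 * max(tau, 1e-12)):
        raise InvalidParameterError("output_times must be integer multiples of tau")
    if np.any(steps <= 0) or np.any(np.diff(steps) <= 0):
        raise InvalidParameterError("output_times must map to increasing positive step counts")
    return steps


def run_ibm(
    config: ScenarioConfig,
    reps: int = 10,
    seed: int | np.random.SeedSequence = 0,
    rounding: str = "round",
) -> IBMResult:
    """Run ``reps`` replicates of the IBM to ``t_end`` and record densities
    at the configured output times (plus ``t = 0``).

    One root seed deterministically spawns independent per-replicate
    streams, so results are reproducible and replicates are uncorrelated.
    """
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = np.array(
        [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(reps)], dtype=np.int64
    )
    state0 = initial_counts(config, rounding=rounding)
    rec = _record_steps(config)
    I, J = state0.N.shape
    T = rec.size + 1
    densities = np.empty((reps, T, I, J))
    x = cell_centres(config.disc.L, config.disc.dx)
    use_kernel = config.growth.name == "arctan"
    for r in range(reps):
        densities[r, 0] = state0.densities()
        if use_kernel:
            out, status, err_site = _kernels.ibm_kernel(
                state0.N.copy(),
                rec,
                config.disc.tau,
                config.disc.dx,
                config.phenotypes.gamma.astype(float),
                config.phenotypes.alpha.astype(float),
                config.phenotypes.omega.astype(float),
                config.pbar,
                child_seeds[r],
            )
            if status == _kernels.STATUS_BAD_PROBABILITY:
                raise ProbabilityError(
                    f"event probability out of range at site {err_site}; "
                    "reduce tau or dx (gamma too large)"
                )
            densities[r, 1:] = out
        else:  # custom growth law: reference path
            rng = np.random.default_rng(child_seeds[r])
            state = state0
            idx = 0
            for k in range(1, int(rec[-1]) + 1):
                state = step(state, config, rng)
                if idx < rec.size and k == rec[idx]:
                    densities[r, idx + 1] = state.densities()
                    idx += 1
    times = np.concatenate([[0.0], np.asarray(config.disc.output_times, dtype=float)])
    return IBMResult(
        times=times,
        densities=densities,
        x=x,
        omega=config.phenotypes.omega.copy(),
        seeds=child_seeds,
    )
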