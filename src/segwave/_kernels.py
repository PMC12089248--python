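"""Numba hot loops for the lattice IBM and the finite-volume PDE solver.

Both kernels hard-code the built-in arctan growth law; configs with a
custom growth law fall back to the (slower) pure-numpy reference paths in
:mod:`segwave.ibm` and :mod:`segwave.pde`.

Status codes returned by the kernels:

* 0 — success
* 1 — an event probability left its admissible range (IBM); the offending
  site index is reported alongside
* 2 — NaN or Inf detected in the state (PDE)
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BAD_PROBABILITY = 1
STATUS_NOT_FINITE = 2


@njit(cache=True)
def _arctan_G(p, pbar):
    return np.arctan(0.1 * (1.0 - p / pbar))


@njit(cache=True)
def ibm_kernel(N, record_steps, tau, dx, gamma, alpha, omega, pbar, seed):
    """Advance the lattice state ``N`` (phenotype x site counts, modified in
    place) and record densities at the absolute step indices ``record_steps``.

    One synchronous step: all probabilities are evaluated from the frozen
    start-of-step state; per site and phenotype the count is split into
    (left, right, stay) movers by a chained-binomial multinomial draw, then
    division/death is drawn with the origin site's pressure and daughters
    (or removals) are applied at the post-move position.  Moves off the
    domain are aborted (the cell stays), which realises zero-flux walls.

    Returns ``(out, status, err_site)`` where ``out[k]`` holds the density
    ``N/dx`` after ``record_steps[k]`` steps.
    """
    np.random.seed(seed)
    I, J = N.shape
    n_rec = record_steps.shape[0]
    out = np.zeros((n_rec, I, J), dtype=np.float64)
    total_steps = record_steps[n_rec - 1]
    Nn = np.zeros((I, J), dtype=np.int64)
    p = np.zeros(J, dtype=np.float64)
    rec = 0
    for step_idx in range(1, total_steps + 1):
        jmax = 0
        for j in range(J):
            acc = 0.0
            for i in range(I):
                if N[i, j] > 0 and j > jmax:
                    jmax = j
                acc += omega[i] * N[i, j]
            p[j] = acc / dx
        hi = jmax + 2 if jmax + 2 < J else J
        for i in range(I):
            for j in range(hi):
                Nn[i, j] = 0
        for j in range(hi):
            pj = p[j]
            dl = pj - p[j - 1] if j > 0 else 0.0
            dr = pj - p[j + 1] if j + 1 < J else 0.0
            g_site_raw = _arctan_G(pj, pbar)
            for i in range(I):
                n_ij = N[i, j]
                if n_ij == 0:
                    continue
                pl = gamma[i] * dl / (2.0 * pbar) if dl > 0.0 else 0.0
                pr = gamma[i] * dr / (2.0 * pbar) if dr > 0.0 else 0.0
                if pl + pr >= 1.0 or pl < 0.0 or pr < 0.0:
                    return out, STATUS_BAD_PROBABILITY, j
                nl = np.random.binomial(n_ij, pl) if pl > 0.0 else 0
                rem = n_ij - nl
                nr = 0
                if pr > 0.0 and rem > 0:
                    nr = np.random.binomial(rem, pr / (1.0 - pl))
                ns = rem - nr
                jl = j - 1 if j > 0 else j
                jr = j + 1 if j + 1 < J else j
                if alpha[i] > 0.0:
                    g = tau * alpha[i] * g_site_raw
                    if g >= 1.0 or g <= -1.0:
                        return out, STATUS_BAD_PROBABILITY, j
                    bl = 0
                    bs = 0
                    br = 0
                    if g > 0.0:
                        if nl > 0:
                            bl = np.random.binomial(nl, g)
                        if ns > 0:
                            bs = np.random.binomial(ns, g)
                        if nr > 0:
                            br = np.random.binomial(nr, g)
                    elif g < 0.0:
                        if nl > 0:
                            bl = -np.random.binomial(nl, -g)
                        if ns > 0:
                            bs = -np.random.binomial(ns, -g)
                        if nr > 0:
                            br = -np.random.binomial(nr, -g)
                    Nn[i, jl] += nl + bl
                    Nn[i, j] += ns + bs
                    Nn[i, jr] += nr + br
                else:
                    Nn[i, jl] += nl
                    Nn[i, j] += ns
                    Nn[i, jr] += nr
        for i in range(I):
            for j in range(hi):
                N[i, j] = Nn[i, j]
        if rec < n_rec and step_idx == record_steps[rec]:
            for i in range(I):
                for j in range(J):
                    out[rec, i, j] = N[i, j] / dx
            rec += 1
    return out, STATUS_OK, -1


@njit(cache=True)
def pde_kernel(n, t, t_target, dx, mu, alpha, omega, pbar, cfl, dt_react_max, neg_tol):
    """Advance the continuum densities ``n`` (modified in place) from time
    ``t`` to ``t_target`` with first-order upwind fluxes and explicit Euler.

    Each step: edge velocity ``u_{j+1/2} = -mu_i (p_{j+1}-p_j)/dx``, flux
    ``u * n_upwind``, zero flux through the boundary edges, then the
    reaction ``n *= 1 + dt alpha_i G(p)`` with the start-of-step pressure.
    The time step obeys ``dt <= cfl dx^2 / (2 max(mu) max(p))`` plus the
    reaction sub-limit, and is truncated to land exactly on ``t_target``.

    Returns ``(t, status)``.
    """
    I, J = n.shape
    mu_max = mu.max()
    p = np.zeros(J, dtype=np.float64)
    flux = np.zeros(J + 1, dtype=np.float64)
    while t < t_target - 1e-12 * (1.0 + abs(t_target)):
        pmax = 0.0
        for j in range(J):
            acc = 0.0
            for i in range(I):
                acc += omega[i] * n[i, j]
            p[j] = acc
            if acc > pmax:
                pmax = acc
        if not np.isfinite(pmax):
            return t, STATUS_NOT_FINITE
        dt = cfl * dx * dx / (2.0 * mu_max * pmax + 1e-300)
        if dt > dt_react_max:
            dt = dt_react_max
        if dt > t_target - t:
            dt = t_target - t
        for i in range(I):
            flux[0] = 0.0
            flux[J] = 0.0
            for j in range(1, J):
                u = -mu[i] * (p[j] - p[j - 1]) / dx
                flux[j] = u * (n[i, j - 1] if u > 0.0 else n[i, j])
            if alpha[i] > 0.0:
                for j in range(J):
                    nv = n[i, j] + dt / dx * (flux[j] - flux[j + 1])
                    nv *= 1.0 + dt * alpha[i] * _arctan_G(p[j], pbar)
                    if nv < 0.0:
                        if nv < -neg_tol[i]:
                            return t, STATUS_NOT_FINITE
                        nv = 0.0
                    n[i, j] = nv
            else:
                for j in range(J):
                    nv = n[i, j] + dt / dx * (flux[j] - flux[j + 1])
                    if nv < 0.0:
                        if nv < -neg_tol[i]:
                            return t, STATUS_NOT_FINITE
                        nv = 0.0
                    n[i, j] = nv
        t += dt
    return t_target, STATUS_OK
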