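"""Measurement layer: level-set tracking, speed fits, masses, supports,
and model-vs-model pressure comparison.

Front speeds are estimated exactly as in the numerical study: track the
rightmost point ``x_level(t)`` where the pressure crosses a fixed level
(0.2, 0.4 or 0.6 times the homeostatic pressure), then fit a straight
line to the trajectory after the transient (by default the second half of
the run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenario import InvalidParameterError

__all__ = [
    "SpeedEstimate",
    "ComparisonReport",
    "track_level",
    "fit_speed",
    "masses",
    "support_endpoints",
    "support_threshold",
    "compare_pressures",
    "DEFAULT_LEVELS",
    "SUPPORT_THRESHOLD_FRACTION",
]

#: pressure levels tracked for speed estimation, as fractions of pbar
DEFAULT_LEVELS = (0.2, 0.4, 0.6)

#: default support threshold as a fraction of the phenotype's density
#: scale pbar/omega_i.  First-order upwind transport leaves exponentially
#: decaying tails ahead of each interface, so the threshold must sit well
#: above rounding level to measure the physical support edge.
SUPPORT_THRESHOLD_FRACTION = 1e-3


def support_threshold(pbar: float, omega) -> np.ndarray:
    """Per-phenotype support threshold ``1e-3 pbar / omega_i``."""
    return SUPPORT_THRESHOLD_FRACTION * pbar / np.asarray(omega, dtype=float)


def track_level(p_series: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Rightmost downward crossing of ``level`` per time slice.

    ``p_series`` is (T, J); returns (T,) positions, located by linear
    interpolation between adjacent grid values, NaN where the level is
    never attained (reported, not fatal).
    """
    p_series = np.atleast_2d(np.asarray(p_series, dtype=float))
    x = np.asarray(x, dtype=float)
    if p_series.shape[1] != x.size:
        raise InvalidParameterError("pressure series and grid sizes differ")
    if level <= 0:
        raise InvalidParameterError("level must be positive")
    T, J = p_series.shape
    out = np.full(T, np.nan)
    for k in range(T):
        p = p_series[k]
        above = np.nonzero(p >= level)[0]
        if above.size == 0:
            continue
        j = above[-1]
        if j + 1 < J and p[j] > p[j + 1]:
            out[k] = x[j] + (x[j + 1] - x[j]) * (p[j] - level) / (p[j] - p[j + 1])
        else:
            out[k] = x[j]
    return out


@dataclass
class SpeedEstimate:
    """A fitted level-set speed with its diagnostics."""

    level: float
    times: np.ndarray
    positions: np.ndarray
    window: tuple[float, float]
    slope: float
    intercept: float
    rms_residual: float
    monotone: bool = True


def fit_speed(
    times: np.ndarray,
    positions: np.ndarray,
    window: tuple[float, float] | None = None,
    level: float = np.nan,
) -> SpeedEstimate:
    """Least-squares slope of a level-set trajectory over ``window``
    (default: the second half of the run, i.e. after the transient)."""
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times.size != positions.size:
        raise InvalidParameterError("times and positions must have equal length")
    if window is None:
        window = (times[-1] / 2.0, times[-1])
    sel = (times >= window[0]) & (times <= window[1]) & np.isfinite(positions)
    if sel.sum() < 3:
        raise InvalidParameterError(
            f"need at least 3 trajectory points in window {window}, got {int(sel.sum())}"
        )
    t, xw = times[sel], positions[sel]
    slope, intercept = np.polyfit(t, xw, 1)
    resid = xw - (slope * t + intercept)
    monotone = bool(np.all(np.diff(xw) >= -1e-9 * max(1.0, abs(xw).max())))
    if not monotone:
        import warnings

        warnings.warn("level-set trajectory is not non-decreasing inside the fit window",
                      stacklevel=2)
    return SpeedEstimate(
        level=level,
        times=t,
        positions=xw,
        window=(float(window[0]), float(window[1])),
        slope=float(slope),
        intercept=float(intercept),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        monotone=monotone,
    )


def masses(n: np.ndarray, dx: float) -> np.ndarray:
    """Per-phenotype masses ``M_i = sum_j n_{i,j} dx`` (midpoint rule,
    consistent with finite-volume cell averages)."""
    n = np.asarray(n, dtype=float)
    if n.ndim == 1:
        n = n[None, :]
    return n.sum(axis=1) * dx


def support_endpoints(
    n: np.ndarray, x: np.ndarray, threshold
) -> tuple[np.ndarray, np.ndarray]:
    """Right endpoints ``X_i`` of each phenotype's support and the offsets
    ``Z_i = X_i - X_1``.

    ``X_i`` is the centre of the rightmost cell with ``n_i > threshold``
    (``threshold`` may be scalar or per-phenotype); NaN for an empty
    support.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    x = np.asarray(x, dtype=float)
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), (n.shape[0],))
    if np.any(thr <= 0):
        raise InvalidParameterError("support threshold must be positive")
    X = np.full(n.shape[0], np.nan)
    for i in range(n.shape[0]):
        idx = np.nonzero(n[i] > thr[i])[0]
        if idx.size:
            X[i] = x[idx[-1]]
    Z = X - X[0]
    return X, Z


@dataclass
class ComparisonReport:
    """Normalised pressure discrepancy between two runs on one grid."""

    x: np.ndarray
    discrepancy: np.ndarray  # |p_A - p_B| / pbar, same shape as the inputs
    sup_norm: float
    region_sup: dict = field(default_factory=dict)
    supports: dict = field(default_factory=dict)


def compare_pressures(
    p_A: np.ndarray,
    p_B: np.ndarray,
    pbar: float,
    x: np.ndarray | None = None,
    interfaces: np.ndarray | None = None,
    interface_radius: float = 1.0,
) -> ComparisonReport:
    """Pointwise ``|p_A - p_B| / pbar`` plus sup-norms.

    The two fields must live on the same grid (no silent interpolation).
    When ``x`` and interface positions are given, sup-norms are also
    reported for the near-interface region (within ``interface_radius`` of
    any interface) and its complement — quantifying that lattice/continuum
    discrepancies concentrate at the interfaces between phenotypes.
    """
    p_A = np.asarray(p_A, dtype=float)
    p_B = np.asarray(p_B, dtype=float)
    if p_A.shape != p_B.shape:
        raise InvalidParameterError(
            f"grid mismatch: shapes {p_A.shape} vs {p_B.shape} (no interpolation performed)"
        )
    if pbar <= 0:
        raise InvalidParameterError("pbar must be positive")
    d = np.abs(p_A - p_B) / pbar
    report = ComparisonReport(
        x=x if x is not None else np.arange(p_A.shape[-1], dtype=float),
        discrepancy=d,
        sup_norm=float(d.max()),
    )
    if x is not None and interfaces is not None:
        x = np.asarray(x, dtype=float)
        interfaces = np.asarray(interfaces, dtype=float)
        interfaces = interfaces[np.isfinite(interfaces)]
        d1 = d if d.ndim == 1 else d.reshape(-1, d.shape[-1]).max(axis=0)
        near = np.zeros(x.size, dtype=bool)
        for xi in interfaces:
            near |= np.abs(x - xi) <= interface_radius
        report.region_sup = {
            "near_interfaces": float(d1[near].max()) if near.any() else np.nan,
            "away_from_interfaces": float(d1[~near].max()) if (~near).any() else np.nan,
        }
        report.supports = {"interfaces": interfaces, "radius": float(interface_radius)}
    return report
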