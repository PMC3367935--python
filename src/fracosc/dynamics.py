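"""Steady states, linear stability, trajectory classification and bifurcation scans.

The linear-stability results here are the classical integer-order ones (the
n > 8 destabilization threshold of the symmetric three-stage Goodwin loop).
For the delayed fractional systems classification is simulation-based: the
solver output is classified from its post-transient peaks, mirroring how
the oscillation/stability claims are established numerically rather than
through a spectral theory of delayed fractional operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .grids import TimeGrid, Trajectory
from .models import GoodwinParams, fractional_delay_goodwin, hill_repression
from .solve import FDESystemSpec, HistorySpec, solve_fde, solve_fdde

__all__ = [
    "StabilityReport", "TrajectoryClass", "BifurcationScan", "SweepCell",
    "goodwin_fixed_point", "goodwin3_stability", "goodwin3_critical_hill",
    "classify_trajectory", "delay_sweep", "order_sweep", "bifurcation_scan",
    "goodwin_hopf_delay",
]

#: default run length (time units) for Goodwin classification runs;
#: long enough to hold >= 5 post-transient cycles at delays up to ~25
GOODWIN_RUN_LENGTH = 1000.0
#: default amplitude-trend slope below which a peak train counts as damped
SLOPE_TOLERANCE = 1e-4
#: coefficient of variation of peak spacing above which motion is irregular
SPACING_CV_THRESHOLD = 0.25


@dataclass(frozen=True)
class StabilityReport:
    """Fixed point, Jacobian spectrum and the resulting stability verdict."""

    fixed_point: np.ndarray
    jacobian_eigenvalues: np.ndarray
    stable: bool
    critical_parameter: Optional[float] = None


@dataclass(frozen=True)
class TrajectoryClass:
    """Post-transient classification of a solved trajectory.

    ``amplitude_trend`` is the least-squares slope of successive peak
    heights per unit time; sustained oscillation requires at least five
    post-transient peaks whose amplitude does not decay.
    """

    label: str  # fixed_point | damped_oscillation | sustained_oscillation | irregular
    amplitude_trend: float
    peak_count: int

    @property
    def sustained(self) -> bool:
        return self.label == "sustained_oscillation"


@dataclass
class SweepCell:
    """One cell of a parameter sweep; solver failures are recorded, not raised."""

    value: float
    result: Optional[TrajectoryClass]
    error: Optional[str] = None


@dataclass
class BifurcationScan:
    """Per-order sets of distinct post-transient local maxima of an observable."""

    alpha_values: np.ndarray
    maxima_per_alpha: list  # raw local maxima arrays (empty where the run failed)
    clusters_per_alpha: list  # merged maxima (distinct attractor branches)
    transient_fraction: float

    def cluster_counts(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters_per_alpha])


# ---------------------------------------------------------------------------
# fixed points and linear stability
# ---------------------------------------------------------------------------

def goodwin_fixed_point(params: GoodwinParams) -> float:
    """Unique non-negative root of ``1 / (1 + x**n) = k2 * x``.

    The left side decreases from 1 and the right side increases from 0, so
    the root exists and is unique; it is bracketed by [0, 1/k2] and polished
    to |residual| < 1e-12.
    """
    n, k2 = params.n, params.k2

    def g(x):
        return 1.0 / (1.0 + x ** n) - k2 * x

    x_star = brentq(g, 0.0, 1.0 / k2, xtol=1e-15, rtol=8.9e-16)
    # one Newton polish for the residual contract
    dg = -n * x_star ** (n - 1) / (1.0 + x_star ** n) ** 2 - k2
    x_star -= g(x_star) / dg
    return float(x_star)


def _goodwin3_jacobian(x3: float, n: float, k: float) -> np.ndarray:
    """Jacobian of the symmetric three-stage loop at its fixed point (production 1,
    degradation k at every stage, Hill repression from stage 3 back to stage 1)."""
    fprime = -n * x3 ** (n - 1) / (1.0 + x3 ** n) ** 2
    return np.array([
        [-k, 0.0, fprime],
        [1.0, -k, 0.0],
        [0.0, 1.0, -k],
    ])


def _goodwin3_fixed_point(n: float, k: float) -> float:
    """Root of ``k**3 * x * (1 + x**n) = 1`` (last-stage value of the symmetric chain)."""
    def g(x):
        return k ** 3 * x * (1.0 + x ** n) - 1.0

    hi = 2.0
    while g(hi) < 0:
        hi *= 2.0
    return brentq(g, 0.0, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)


def goodwin3_stability(n: float, k: float) -> StabilityReport:
    """Linear stability of the symmetric three-variable Goodwin loop at rate scale ``k``."""
    x3 = _goodwin3_fixed_point(n, k)
    x1 = hill_repression(x3, n) / k
    x2 = x1 / k
    eig = np.linalg.eigvals(_goodwin3_jacobian(x3, n, k))
    return StabilityReport(
        fixed_point=np.array([x1, x2, x3]),
        jacobian_eigenvalues=eig,
        stable=bool(np.all(eig.real < 0)),
    )


def goodwin3_critical_hill(
    symmetric_rates: bool = True,
    tol: float = 1e-7,
    k_grid: Optional[np.ndarray] = None,
) -> float:
    """Infimum Hill coefficient destabilizing the symmetric three-variable Goodwin loop.

    For each candidate n the loop is tested over a range of rate scalings
    k (the fixed point and the Jacobian spectrum depend on k); n is
    unstable if *some* scaling yields an eigenvalue with non-negative real
    part.  Bisection on n converges to the classical threshold 8 — the
    value the closed-form secant condition ``n = sec(pi/3)**3`` gives,
    because the loop log-gain ``n * x**n / (1 + x**n)`` approaches n only
    as the scaling k tends to 0.

    Only the symmetric-rate regime is implemented; the asymmetric critical
    surface is out of scope.
    """
    if not symmetric_rates:
        raise NotImplementedError("asymmetric-rate critical Hill surface not implemented")
    if k_grid is None:
        # smaller k raises the achievable loop gain toward its supremum n
        k_grid = np.logspace(-6, -0.5, 40)

    def unstable(n: float) -> bool:
        return any(not goodwin3_stability(n, k).stable for k in k_grid)

    lo, hi = 1.0, 16.0
    if unstable(lo) or not unstable(hi):
        raise RuntimeError("bisection bracket for the critical Hill coefficient failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if unstable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def goodwin_hopf_delay(params: GoodwinParams) -> float:
    """Critical delay of the classical (alpha = 1) delayed Goodwin model.

    Linearizing ``x' = f(x(t - tau)) - k2 x`` about the fixed point gives
    the characteristic equation ``lambda = -k2 - b exp(-lambda tau)`` with
    feedback gain ``b = |f'(x*)|``; the roots first cross the imaginary
    axis at ``omega = sqrt(b**2 - k2**2)``, ``tau_c = arccos(-k2/b) / omega``.
    Requires b > k2 (otherwise no delay destabilizes; returns inf).
    """
    x_star = goodwin_fixed_point(params)
    n, k2 = params.n, params.k2
    b = n * x_star ** (n - 1) / (1.0 + x_star ** n) ** 2
    if b <= k2:
        return float("inf")
    omega = np.sqrt(b * b - k2 * k2)
    return float(np.arccos(-k2 / b) / omega)


# ---------------------------------------------------------------------------
# trajectory classification
# ---------------------------------------------------------------------------

def classify_trajectory(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    tolerance: float = 1e-3,
    observable: int = 0,
    slope_tolerance: float = SLOPE_TOLERANCE,
    spacing_cv_threshold: float = SPACING_CV_THRESHOLD,
) -> TrajectoryClass:
    """Label the post-transient motion of one trajectory coordinate.

    After discarding the leading ``transient_fraction`` of samples:

    * range below ``tolerance`` (relative to the signal scale) -> ``fixed_point``;
    * otherwise local maxima are collected; fewer than five peaks with the
      tail settling -> ``fixed_point``, fewer than five without settling ->
      ``damped_oscillation``;
    * erratic peak spacing (coefficient of variation above the threshold)
      -> ``irregular``;
    * otherwise the least-squares slope of peak heights over time decides:
      non-decaying (>= -slope_tolerance per unit time) ->
      ``sustained_oscillation``, else ``damped_oscillation``.
    """
    if traj.blown_up:
        raise ValueError("cannot classify a blown-up trajectory")
    tail = traj.post_transient(transient_fraction)
    x = tail.component(observable)
    t = tail.times
    scale = max(1.0, float(np.max(np.abs(x))))
    rng = float(np.ptp(x))
    if rng < tolerance * scale:
        return TrajectoryClass("fixed_point", 0.0, 0)

    peaks, _ = find_peaks(x, prominence=tolerance * scale)
    if peaks.size < 5:
        # few peaks: settling tail means relaxation, otherwise slow damping
        last_quarter = x[3 * x.size // 4:]
        if np.ptp(last_quarter) < tolerance * scale:
            return TrajectoryClass("fixed_point", 0.0, int(peaks.size))
        return TrajectoryClass("damped_oscillation", 0.0, int(peaks.size))

    heights = x[peaks]
    times = t[peaks]
    slope = float(np.polyfit(times, heights, 1)[0])
    spacing = np.diff(times)
    cv = float(np.std(spacing) / np.mean(spacing))
    if cv > spacing_cv_threshold:
        return TrajectoryClass("irregular", slope, int(peaks.size))
    if slope >= -slope_tolerance:
        return TrajectoryClass("sustained_oscillation", slope, int(peaks.size))
    return TrajectoryClass("damped_oscillation", slope, int(peaks.size))


# ---------------------------------------------------------------------------
# sweeps and bifurcation scans
# ---------------------------------------------------------------------------

def _solve_goodwin(params: GoodwinParams, run_length: float, h: float,
                   method: str, init: Optional[float]) -> Trajectory:
    spec = fractional_delay_goodwin(params)
    grid = TimeGrid.from_duration(run_length, h)
    if init is None:
        init = 0.1  # low initial repressor: transcription starts near full rate
    if params.tau > 0:
        return solve_fdde(spec, HistorySpec.constant([init]), grid, method=method)
    return solve_fde(spec, [init], grid, method=method)


def delay_sweep(
    params: GoodwinParams,
    tau_values: Sequence[float],
    run_length: float = GOODWIN_RUN_LENGTH,
    h: float = 0.02,
    method: str = "abm",
    init: Optional[float] = None,
    transient_fraction: float = 0.5,
) -> list[SweepCell]:
    """Classify the delayed Goodwin model across a list of delays."""
    cells = []
    for tau in tau_values:
        try:
            p = GoodwinParams(n=params.n, k2=params.k2, tau=float(tau),
                              alpha=params.alpha)
            traj = _solve_goodwin(p, run_length, h, method, init)
            cells.append(SweepCell(float(tau),
                                   classify_trajectory(traj, transient_fraction)))
        except Exception as exc:  # recorded, not raised
            cells.append(SweepCell(float(tau), None, str(exc)))
    return cells


def order_sweep(
    params: GoodwinParams,
    alpha_values: Sequence[float],
    run_length: float = GOODWIN_RUN_LENGTH,
    h: float = 0.02,
    method: str = "abm",
    init: Optional[float] = None,
    transient_fraction: float = 0.5,
) -> list[SweepCell]:
    """Classify the delayed Goodwin model across a list of fractional orders."""
    cells = []
    for alpha in alpha_values:
        try:
            p = GoodwinParams(n=params.n, k2=params.k2, tau=params.tau,
                              alpha=float(alpha))
            traj = _solve_goodwin(p, run_length, h, method, init)
            cells.append(SweepCell(float(alpha),
                                   classify_trajectory(traj, transient_fraction)))
        except Exception as exc:
            cells.append(SweepCell(float(alpha), None, str(exc)))
    return cells


def _merge_maxima(maxima: np.ndarray, merge_tol: float) -> np.ndarray:
    """Collapse local maxima closer than ``merge_tol`` into cluster centers."""
    if maxima.size == 0:
        return maxima
    vals = np.sort(maxima)
    clusters = [[vals[0]]]
    for v in vals[1:]:
        if v - clusters[-1][-1] <= merge_tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return np.array([np.mean(c) for c in clusters])


def bifurcation_scan(
    spec_factory: Callable[[float], FDESystemSpec],
    alpha_values: Sequence[float],
    observable: int = 0,
    transient_fraction: float = 0.75,
    run_length: float = 2000.0,
    h: float = 0.02,
    method: str = "oustaloup",
    init: Sequence[float] = (1.0, 1.0, 1.0),
    merge_tol: float = 1e-3,
) -> BifurcationScan:
    """Post-transient local-maxima diagram of an observable versus the order.

    One merged cluster of maxima marks period-one motion, two mark
    period-two, three mark a period-three window, and a large cluster count
    marks a chaotic candidate.  Blown-up or failed cells are recorded as
    empty maxima sets.
    """
    alpha_values = np.asarray(sorted(alpha_values), dtype=float)
    if np.any(alpha_values <= 0) or np.any(alpha_values > 1):
        raise ValueError("orders must lie in (0, 1]")
    maxima_sets, cluster_sets = [], []
    for alpha in alpha_values:
        try:
            spec = spec_factory(float(alpha))
            grid = TimeGrid.from_duration(run_length, h)
            traj = solve_fde(spec, np.asarray(init, float)[: spec.dimension],
                             grid, method=method)
            if traj.blown_up:
                raise RuntimeError("trajectory blew up")
            x = traj.post_transient(transient_fraction).component(observable)
            peaks, _ = find_peaks(x, prominence=merge_tol)
            maxima = x[peaks]
        except Exception:
            maxima = np.array([])
        maxima_sets.append(maxima)
        cluster_sets.append(_merge_maxima(maxima, merge_tol))
    return BifurcationScan(alpha_values, maxima_sets, cluster_sets,
                           transient_fraction)
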