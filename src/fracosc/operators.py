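"""Left-sided fractional operators of order 0 < alpha <= 1.

The Riemann–Liouville integral is the common foundation: it replaces the
n-fold repeated integral by a convolution with the power-law kernel
``(t - s)**(alpha - 1) / Gamma(alpha)``.  The Caputo derivative is the
(1 - alpha)-order integral of the ordinary first derivative, which keeps
integer-order initial conditions meaningful for dynamical models.  Orders
above 1 are rejected throughout: a state increment cannot be assigned a
time increment shorter than the one actually observed, so only the "slow"
branch alpha in (0, 1] is modelled.

Discretizations use the product-trapezoidal rule (exact for piecewise
linear integrands against the power kernel), the same quadrature family as
the predictor–corrector solver in :mod:`fracosc.solve`.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gamma as _gamma

from .grids import SampledFunction

__all__ = [
    "validate_order",
    "memory_kernel_weight",
    "riemann_liouville_integral",
    "caputo_derivative",
    "mittag_leffler",
    "trapezoid_weights",
]


def validate_order(alpha: float) -> float:
    """Check that a fractional order lies in the admissible range (0, 1]."""
    alpha = float(alpha)
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"fractional order must satisfy 0 < alpha <= 1, got {alpha}")
    return alpha


def memory_kernel_weight(alpha: float, elapsed):
    """Weight ``u**(alpha-1) / Gamma(alpha)`` assigned to a state ``u`` time units in the past.

    This is the convolution kernel through which a fractional integral
    averages the history of its integrand: for alpha = 1 every past instant
    carries the same weight 1 (no memory decay); for alpha < 1 the weight
    decays with elapsed time, the "fading memory" picture, and decays more
    slowly the closer alpha is to 1.

    Parameters
    ----------
    alpha : float
        Order in (0, 1].
    elapsed : float or array_like
        Elapsed time u >= 0.  For alpha < 1 the kernel is singular at
        u = 0, so zero elapsed time is rejected; the caller decides how to
        handle the limit.
    """
    alpha = validate_order(alpha)
    u = np.asarray(elapsed, dtype=float)
    if np.any(u < 0):
        raise ValueError("elapsed time must be non-negative")
    if alpha < 1.0 and np.any(u == 0):
        raise ZeroDivisionError(
            "memory kernel is singular at zero elapsed time for alpha < 1"
        )
    w = u ** (alpha - 1.0) / _gamma(alpha)
    return float(w) if np.isscalar(elapsed) else w


def trapezoid_weights(alpha: float, n: int) -> np.ndarray:
    """Product-trapezoidal convolution weights ``c_m`` for the power kernel.

    ``c_0 = 1`` and ``c_m = (m+1)**(a+1) + (m-1)**(a+1) - 2*m**(a+1)`` for
    m >= 1, where a = alpha.  These are the interior weights of the
    second-order accurate quadrature for ``I^alpha`` on a uniform grid; the
    boundary weight at j = 0 is handled separately by the callers.
    """
    m = np.arange(n + 1, dtype=float)
    c = np.empty(n + 1)
    c[0] = 1.0
    if n >= 1:
        mm = m[1:]
        c[1:] = (mm + 1) ** (alpha + 1) + (mm - 1) ** (alpha + 1) - 2 * mm ** (alpha + 1)
    return c


def riemann_liouville_integral(f: SampledFunction, alpha: float) -> SampledFunction:
    """Fractional integral ``(I^alpha f)(t_k)`` on the sample grid of ``f``.

    Computes ``(1/Gamma(alpha)) * int_0^t (t-s)**(alpha-1) f(s) ds`` by the
    product-trapezoidal rule, which integrates the kernel exactly against a
    piecewise-linear interpolant of ``f``.  The value at t = 0 is 0.
    """
    alpha = validate_order(alpha)
    vals = f.values
    n = vals.size - 1
    if n < 1:
        raise ValueError("grid must contain at least two points")
    h = f.grid.h

    # a_{0,k} boundary weights and the Toeplitz interior handled by one FFT
    # convolution: sum_{j=1}^{k} c_{k-j} f_j  (c_0 multiplies f_k itself).
    k = np.arange(n + 1, dtype=float)
    a0 = np.zeros(n + 1)
    a0[1:] = (k[1:] - 1) ** (alpha + 1) - (k[1:] - 1 - alpha) * k[1:] ** alpha

    c = trapezoid_weights(alpha, n)
    conv = fftconvolve(c, vals[1:])[:n]  # entry k-1 = sum_{m=0}^{k-1} c_m f_{k-m}
    out = np.zeros(n + 1)
    out[1:] = (h ** alpha / _gamma(alpha + 2)) * (a0[1:] * vals[0] + conv)
    return SampledFunction(grid=f.grid, values=out)


def caputo_derivative(f: SampledFunction, alpha: float) -> SampledFunction:
    """Caputo derivative ``(D^alpha f)(t_k)`` on the sample grid of ``f``.

    For alpha = 1 this is the ordinary first derivative (second-order
    central differences); for alpha < 1 it is the (1 - alpha)-order
    Riemann–Liouville integral of that derivative, so the derivative of any
    constant is identically zero.
    """
    alpha = validate_order(alpha)
    if f.values.size < 3:
        raise ValueError("Caputo derivative needs at least three grid points")
    dfdt = np.gradient(f.values, f.grid.h, edge_order=2)
    if alpha == 1.0:
        return SampledFunction(grid=f.grid, values=dfdt)
    return riemann_liouville_integral(
        SampledFunction(grid=f.grid, values=dfdt), 1.0 - alpha
    )


def mittag_leffler(alpha: float, z, max_terms: int = 400, tol: float = 1e-14):
    """One-parameter Mittag-Leffler function ``E_alpha(z) = sum z^k / Gamma(alpha k + 1)``.

    Direct series summation, adequate for the moderate arguments arising in
    fractional relaxation tests (``E_alpha(-t**alpha)`` solves
    ``D^alpha x = -x``).  ``E_1(z) = exp(z)``.
    """
    alpha = float(alpha)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z, dtype=float)
    term = np.ones_like(z, dtype=float)
    out += term
    for k in range(1, max_terms):
        term = z ** k / _gamma(alpha * k + 1)
        out += term
        if np.all(np.abs(term) < tol * np.maximum(np.abs(out), 1.0)):
            break
    return float(out) if np.isscalar(z) or z.ndim == 0 else out
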