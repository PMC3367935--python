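"""Genetic oscillator models: the Goodwin family, the Rössler system, and
transcriptional reinitiation survival.

The Goodwin oscillator is the minimal negative-autoregulation circuit: a
gene product represses its own synthesis through a Hill function while
decaying linearly.  The normalized one-variable form is

    dx/dt = 1 / (1 + x**n) - k2 * x

which has a globally attracting steady state — it never oscillates on its
own.  Oscillation needs slow dynamics, supplied either by an explicit
transcriptional delay tau (the delayed repression acts through
``x(t - tau)``) or by chaining intermediate stages (the classical
three-variable loop, which destabilizes only for Hill coefficient n > 8).
When transcription is globally slow — silent intervals appended to each
transcriptional event stretch every time increment — the time derivative
becomes a Caputo derivative of order alpha < 1, giving the fractional
delay Goodwin oscillator, a dual-memory system (power-law order memory
plus explicit delay).

The Rössler system stands in for a coupled, potentially chaotic genetic
network (activator amplification with two parallel negative feedback
loops); its commensurate fractional version shares one order alpha across
all three equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .operators import validate_order
from .solve import FDESystemSpec

__all__ = [
    "GoodwinParams", "RosslerParams", "ReinitiationModel",
    "hill_repression", "goodwin_rhs", "fractional_delay_goodwin",
    "rossler_system", "reinitiation_survival", "PRESETS", "preset_spec",
]


@dataclass(frozen=True)
class GoodwinParams:
    """Parameters of the (fractional, delayed) one-variable Goodwin model.

    The synthesis scale is normalized to 1; ``k2`` is the linear
    degradation rate, ``n`` the Hill coefficient of the repression,
    ``tau`` the transcriptional delay and ``alpha`` the Caputo order.
    Defaults put the delayed alpha = 0.9 model comfortably in its
    oscillatory regime: n = 10 exceeds the classical nonlinearity
    threshold, and k2 = 0.1 keeps the degradation timescale "properly
    balanced" (a too-large k2 suppresses oscillation).
    """

    n: float = 10.0
    k2: float = 0.1
    tau: float = 0.0
    alpha: float = 1.0
    synthesis_scale: float = 1.0

    def __post_init__(self) -> None:
        validate_order(self.alpha)
        if self.synthesis_scale != 1.0:
            raise ValueError("synthesis scale is fixed at 1 (normalized model)")
        if self.n < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if self.k2 <= 0:
            raise ValueError("degradation rate k2 must be positive")
        if self.tau < 0:
            raise ValueError("delay tau must be non-negative")


@dataclass(frozen=True)
class RosslerParams:
    """Rössler parameters with a commensurate fractional order.

    The default ``(a, b, c) = (0.15, 0.20, 10.0)`` is the benchmark set of
    the standard Lyapunov-estimation literature (chaotic at alpha = 1 with
    largest Lyapunov exponent near +0.1); ``(0.2, 0.2, 5.7)`` is the other
    classic choice, available as the ``rossler-classic`` preset.
    """

    a: float = 0.15
    b: float = 0.20
    c: float = 10.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        validate_order(self.alpha)
        if self.c <= 0:
            raise ValueError("c must be positive")


@dataclass(frozen=True)
class ReinitiationModel:
    """Memoryless decay of transcriptional reinitiation capability.

    ``gamma`` is the probability per unit time that a gene which is still
    competent for reinitiation loses that competence during a silent
    interval; survival over an interval dt is exp(-gamma * dt).
    """

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def hill_repression(x, n: float):
    """Normalized repressive Hill (Michaelis–Menten type) synthesis rate ``1 / (1 + x**n)``.

    Monotone non-increasing in the repressor level x, equal to 1 with no
    repressor and 1/2 at the half-maximal point x = 1.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("repressor concentration must be non-negative")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    out = 1.0 / (1.0 + xa ** n)
    return float(out) if np.isscalar(x) else out


def goodwin_rhs(state, params: GoodwinParams, rates=None) -> np.ndarray:
    """Instantaneous rates of the 1-, 2- or 3-variable Goodwin chain.

    The first stage is synthesized at a Hill-repressed rate controlled by
    the *last* variable (closing the negative loop) and degraded linearly;
    each downstream stage is produced linearly from its predecessor and
    degraded linearly.  ``rates`` optionally gives per-stage
    (production, degradation) pairs; by default the chain is symmetric:
    every degradation rate equals ``params.k2`` and every production rate
    equals 1.
    """
    x = np.atleast_1d(np.asarray(state, dtype=float))
    dim = x.size
    if dim not in (1, 2, 3):
        raise ValueError("Goodwin chain dimension must be 1, 2 or 3")
    if np.any(x < 0):
        raise ValueError("Goodwin state components must be non-negative")
    if rates is None:
        prod = np.ones(dim)
        deg = np.full(dim, params.k2)
    else:
        prod, deg = (np.asarray(r, float) for r in rates)
    out = np.empty(dim)
    out[0] = prod[0] * hill_repression(x[-1], params.n) - deg[0] * x[0]
    for i in range(1, dim):
        out[i] = prod[i] * x[i - 1] - deg[i] * x[i]
    return out


def fractional_delay_goodwin(params: GoodwinParams) -> FDESystemSpec:
    """System spec for ``D^alpha x(t) = 1 / (1 + x(t - tau)**n) - k2 * x(t)``.

    The delay acts only in the synthesis term (delayed repression: the
    silent interval retards the inhibitor from reaching the promoter);
    degradation sees the present value.  With alpha = 1 and tau = 0 this
    is exactly the classical one-variable Goodwin model.
    """
    n, k2, tau = params.n, params.k2, params.tau

    def rhs(t, x, x_del, p):
        x_eff = x if x_del is None else x_del
        # clip guards the Hill term against tiny negative quadrature noise
        return np.array([
            hill_repression(max(x_eff[0], 0.0), n) - k2 * x[0]
        ])

    return FDESystemSpec(dimension=1, rhs=rhs, alpha=params.alpha, delay=tau,
                         params={"n": n, "k2": k2, "tau": tau}, labels=("x",))


def rossler_system(params: RosslerParams) -> FDESystemSpec:
    """Commensurate fractional Rössler system.

    ``D^alpha x = -y - z``, ``D^alpha y = x + a y``,
    ``D^alpha z = b + z (x - c)``; one shared order alpha.
    """
    a, b, c = params.a, params.b, params.c

    def rhs(t, s, s_del, p):
        x, y, z = s
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    return FDESystemSpec(dimension=3, rhs=rhs, alpha=params.alpha, delay=0.0,
                         params={"a": a, "b": b, "c": c}, labels=("x", "y", "z"))


def rossler_equilibria(params: RosslerParams) -> np.ndarray:
    """Closed-form fixed points of the Rössler flow (roots of the quadratic in z)."""
    a, b, c = params.a, params.b, params.c
    disc = c * c - 4 * a * b
    if disc < 0:
        return np.empty((0, 3))
    eq = []
    for sgn in (+1, -1):
        z = (c + sgn * math.sqrt(disc)) / (2 * a)
        eq.append([a * z, -z, z])
    return np.asarray(eq)


def reinitiation_survival(model: ReinitiationModel, interval) -> float:
    """Probability ``exp(-gamma * interval)`` that reinitiation capability survives
    a silent interval; the complement is the probability of decaying to de novo
    initiation."""
    t = np.asarray(interval, dtype=float)
    if np.any(t < 0):
        raise ValueError("interval must be non-negative")
    out = np.exp(-model.gamma * t)
    return float(out) if np.isscalar(interval) else out


def _goodwin1(**kw) -> FDESystemSpec:
    return fractional_delay_goodwin(GoodwinParams(tau=0.0, alpha=1.0, **kw))


def _goodwin3(n: float = 10.0, k2: float = 0.1) -> FDESystemSpec:
    p = GoodwinParams(n=n, k2=k2)

    def rhs(t, s, s_del, prm):
        return goodwin_rhs(np.maximum(s, 0.0), p)

    return FDESystemSpec(dimension=3, rhs=rhs, alpha=1.0, delay=0.0,
                         params={"n": n, "k2": k2}, labels=("x1", "x2", "x3"))


#: named model presets addressable from the CLI and config files
PRESETS = {
    "goodwin1": lambda **kw: _goodwin1(**kw),
    "goodwin3": lambda **kw: _goodwin3(**kw),
    "goodwin-frac-delay": lambda **kw: fractional_delay_goodwin(
        GoodwinParams(**{"alpha": 0.9, "tau": 20.0, **kw})),
    "rossler": lambda **kw: rossler_system(RosslerParams(**{"alpha": 1.0, **kw})),
    "rossler-frac": lambda **kw: rossler_system(RosslerParams(**{"alpha": 0.95, **kw})),
    "rossler-classic": lambda **kw: rossler_system(
        RosslerParams(**{"a": 0.2, "b": 0.2, "c": 5.7, **kw})),
}


def preset_spec(name: str, **overrides) -> FDESystemSpec:
    """Instantiate a named model preset, applying parameter overrides."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return factory(**overrides)
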