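"""Deterministic synthetic series and trajectories for testing the analysis layer.

Every fixture is reproducible: the same spec and seed give bit-identical
output.  The logistic map at full chaos (r = 4) has the known exact
Lyapunov exponent ln 2, making it the standard oracle for the
divergence-based estimator; sinusoids and damped sinusoids exercise the
periodic and decaying branches of the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grids import TimeGrid, Trajectory
from .models import preset_spec
from .solve import solve_fde

__all__ = ["FixtureSpec", "generate_fixture"]

KINDS = ("logistic_map", "sinusoid", "damped_sinusoid", "white_noise",
         "canned_trajectory")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic series or trajectory."""

    kind: str
    length: int = 1000
    parameters: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.length < 1:
            raise ValueError("length must be positive")


def generate_fixture(spec: FixtureSpec):
    """Materialize a fixture spec into a numpy series (or a Trajectory).

    ``logistic_map``: x_{k+1} = r x_k (1 - x_k), r = 4 by default, x0 either
    given explicitly or drawn (seeded) from (0.1, 0.9).
    ``sinusoid`` / ``damped_sinusoid``: A sin(2 pi t / T + phase), the damped
    variant multiplied by exp(-decay * t); sample period dt.
    ``white_noise``: i.i.d. Gaussian draws with the given sigma.
    ``canned_trajectory``: a short deterministic solver run of a named model
    preset (default: the integer-order Rössler system).
    """
    p = dict(spec.parameters)
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "logistic_map":
        r = p.get("r", 4.0)
        x = np.empty(spec.length)
        x[0] = p.get("x0", rng.uniform(0.1, 0.9))
        for k in range(spec.length - 1):
            x[k + 1] = r * x[k] * (1.0 - x[k])
        return x

    if spec.kind in ("sinusoid", "damped_sinusoid"):
        amplitude = p.get("amplitude", 1.0)
        period = p.get("period", 50.0)
        phase = p.get("phase", 0.0)
        dt = p.get("dt", 1.0)
        t = dt * np.arange(spec.length)
        x = amplitude * np.sin(2 * np.pi * t / period + phase)
        if spec.kind == "damped_sinusoid":
            x = x * np.exp(-p.get("decay", 0.01) * t)
        return x

    if spec.kind == "white_noise":
        return p.get("sigma", 1.0) * rng.standard_normal(spec.length)

    # canned_trajectory
    model = p.pop("model", "rossler")
    h = p.pop("h", 0.05)
    method = p.pop("method", "oustaloup")
    init = p.pop("init", (1.0, 1.0, 1.0))
    sys_spec = preset_spec(model, **p)
    grid = TimeGrid(h=h, n_steps=spec.length - 1)
    return solve_fde(sys_spec, np.asarray(init, float)[: sys_spec.dimension],
                     grid, method=method)
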