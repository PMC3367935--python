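"""Uniform time grids, sampled scalar functions and solution trajectories.

Everything downstream of the solvers speaks ``Trajectory``: a uniformly
sampled multivariate time series plus the metadata needed to reproduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = ["TimeGrid", "SampledFunction", "Trajectory"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid ``t_k = k * h`` for ``k = 0 .. n_steps``.

    The initial time is pinned at 0: all fractional operators here are
    left-sided with lower terminal 0, so the grid origin is part of the
    operator definition, not a free choice.
    """

    h: float
    n_steps: int

    t0: float = 0.0  # fixed; left-side operators start at the origin

    def __post_init__(self) -> None:
        if not (self.h > 0):
            raise ValueError(f"step h must be positive, got {self.h}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.t0 != 0.0:
            raise ValueError("left-side operators require t0 == 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_steps + 1)

    @property
    def t_end(self) -> float:
        return self.t0 + self.h * self.n_steps

    @classmethod
    def from_duration(cls, t_end: float, h: float) -> "TimeGrid":
        """Grid covering ``[0, t_end]`` with step ``h`` (t_end rounded up to a multiple of h)."""
        n = int(np.ceil(round(t_end / h, 9)))
        return cls(h=h, n_steps=max(n, 1))


@dataclass(frozen=True)
class SampledFunction:
    """Scalar function sampled on a :class:`TimeGrid` (one value per node)."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.grid.n_steps + 1:
            raise ValueError(
                f"values must be 1-d with {self.grid.n_steps + 1} entries, "
                f"got shape {vals.shape}"
            )
        object.__setattr__(self, "values", vals)


@dataclass
class Trajectory:
    """Solution of a (fractional, possibly delayed) system on a uniform grid.

    ``states`` has shape ``(n_steps + 1, dimension)``.  A solver that hits a
    non-finite or runaway state truncates the trajectory and sets
    ``blown_up`` — instability is a reportable outcome, not a crash.
    """

    grid: TimeGrid
    states: np.ndarray
    labels: Sequence[str] = ()
    meta: Mapping[str, Any] = field(default_factory=dict)
    blown_up: bool = False

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim == 1:
            states = states[:, None]
        self.states = states
        if not self.labels:
            self.labels = tuple("xyz"[i] if states.shape[1] <= 3 else f"x{i}"
                                for i in range(states.shape[1]))
        if not self.blown_up and states.shape[0] != self.grid.n_steps + 1:
            raise ValueError("complete trajectory must cover the whole grid")
        if not self.blown_up and not np.all(np.isfinite(states)):
            raise ValueError("non-finite states in a trajectory not flagged as blown up")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times[: self.states.shape[0]]

    @property
    def dimension(self) -> int:
        return self.states.shape[1]

    def component(self, index_or_label: int | str) -> np.ndarray:
        if isinstance(index_or_label, str):
            index_or_label = list(self.labels).index(index_or_label)
        return self.states[:, index_or_label]

    def post_transient(self, transient_fraction: float) -> "Trajectory":
        """Drop the leading ``transient_fraction`` of samples (grid restarts at 0)."""
        if not 0 <= transient_fraction < 1:
            raise ValueError("transient_fraction must be in [0, 1)")
        n = self.states.shape[0]
        start = int(np.floor(n * transient_fraction))
        kept = self.states[start:]
        grid = TimeGrid(h=self.grid.h, n_steps=kept.shape[0] - 1)
        return Trajectory(grid=grid, states=kept, labels=self.labels,
                          meta=dict(self.meta), blown_up=self.blown_up)
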