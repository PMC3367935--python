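"""Band-limited rational approximation of fractional operators (Oustaloup recursive filter).

The recursive filter places ``2*n_cells + 1`` interlaced real zeros and
poles, geometrically spaced across a frequency band ``[w_low, w_high]``, so
that the rational transfer function tracks ``s**alpha`` over that band.
Because the plain filter is biproper (equal numerator and denominator
degree), feeding its output algebraically back into a model creates an
algebraic loop; a first-order low-pass section is therefore appended to the
*integrator* form to make it strictly proper before it is used inside a
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operators import validate_order

__all__ = ["OustaloupApprox", "oustaloup_filter"]

#: default approximation band (rad per unit time) and number of cells
DEFAULT_W_LOW = 1e-3
DEFAULT_W_HIGH = 1e3
DEFAULT_N_CELLS = 5


@dataclass(frozen=True)
class OustaloupApprox:
    """Zero/pole/gain approximation of the differentiator ``s**alpha``.

    ``zeros``/``poles`` are the 2*n_cells + 1 roots of the plain recursive
    filter (all real and strictly negative); ``lowpass_cutoff`` is the
    corner of the first-order section appended when the inverse (integrator)
    realization is requested.
    """

    alpha: float
    w_low: float
    w_high: float
    n_cells: int
    zeros: np.ndarray
    poles: np.ndarray
    gain: float
    lowpass_cutoff: float

    def __post_init__(self) -> None:
        if np.any(np.real(self.poles) >= 0):
            raise ValueError("Oustaloup poles must be strictly stable")
        if len(self.zeros) != len(self.poles) or len(self.poles) != 2 * self.n_cells + 1:
            raise ValueError("filter must have 2*n_cells + 1 zero/pole pairs")

    def frequency_response(self, w) -> np.ndarray:
        """Complex response of the ``s**alpha`` approximant at frequencies ``w`` (rad/time)."""
        s = 1j * np.asarray(w, dtype=float)
        num = np.prod(s[..., None] - self.zeros, axis=-1)
        den = np.prod(s[..., None] - self.poles, axis=-1)
        return self.gain * num / den

    def integrator_modes(self) -> tuple[np.ndarray, np.ndarray]:
        """Diagonal (partial-fraction) realization of the strictly proper integrator.

        The integrator ``s**-alpha`` is the reciprocal filter (zeros and
        poles swapped, reciprocal gain) times the appended low-pass
        ``wc / (s + wc)``.  Returns ``(pole_values, residues)`` such that
        ``I(s) = sum_i residues[i] / (s - pole_values[i])``.
        """
        p = np.concatenate([self.zeros, [-self.lowpass_cutoff]])  # integrator poles
        z = self.poles                                            # integrator zeros
        k = self.lowpass_cutoff / self.gain
        res = np.empty_like(p)
        for i, pi in enumerate(p):
            others = np.delete(p, i)
            res[i] = k * np.prod(pi - z) / np.prod(pi - others)
        return p, res


def oustaloup_filter(
    alpha: float,
    w_low: float = DEFAULT_W_LOW,
    w_high: float = DEFAULT_W_HIGH,
    n_cells: int = DEFAULT_N_CELLS,
    lowpass_cutoff: float | None = None,
) -> OustaloupApprox:
    """Build the recursive zero/pole/gain approximation of ``s**alpha`` on ``[w_low, w_high]``.

    Zeros and poles follow the standard recursive spacing

    ``w'_k = w_low * r**((k + n + (1 - alpha)/2) / (2n + 1))`` (zeros),
    ``w_k  = w_low * r**((k + n + (1 + alpha)/2) / (2n + 1))`` (poles),

    for ``k = -n .. n`` with ``r = w_high / w_low``; the gain is normalized
    so that the magnitude at the geometric band center equals
    ``|(i w)**alpha|`` exactly.  ``lowpass_cutoff`` defaults to ``w_high``.
    """
    alpha = validate_order(alpha)
    if not (0 < w_low < w_high):
        raise ValueError("need 0 < w_low < w_high")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if lowpass_cutoff is None:
        lowpass_cutoff = w_high
    if lowpass_cutoff < w_high:
        raise ValueError("low-pass cutoff must not cut into the approximation band")

    n = n_cells
    r = w_high / w_low
    k = np.arange(-n, n + 1, dtype=float)
    zeros = -w_low * r ** ((k + n + (1 - alpha) / 2) / (2 * n + 1))
    poles = -w_low * r ** ((k + n + (1 + alpha) / 2) / (2 * n + 1))

    w_center = np.sqrt(w_low * w_high)
    s = 1j * w_center
    resp_unit = np.prod(s - zeros) / np.prod(s - poles)
    gain = float(w_center ** alpha / np.abs(resp_unit))

    return OustaloupApprox(
        alpha=alpha, w_low=w_low, w_high=w_high, n_cells=n_cells,
        zeros=zeros, poles=poles, gain=gain, lowpass_cutoff=float(lowpass_cutoff),
    )
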