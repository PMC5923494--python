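"""Perimeter-fraction correction for cell-to-cell transmission.

When a virus spreads only between adjacent stationary cells, newly
infected cells appear at the rim of a growing focus.  Cells completely
enclosed by other infected cells no longer contribute to cell-to-cell
(CC) transmission, so the classical mass-action term ``beta_c * I * T``
overcounts the transmitting population.  This module provides the
correction factor ``fc(I)`` — the fraction of infected cells in a focus
of size ``I`` that still border at least one uninfected cell — under the
idealization of radial (ring-by-ring) focus growth on a lattice with
``k`` neighbors per cell.

For a focus that has completed ``n`` expansion rings,

    fc(n, k) = 2 k n / (k n^2 + k n + 2),          (ring fraction)
    I(n, k)  = (k/2) n^2 + (k/2) n + 1,            (focus size)

and eliminating ``n`` gives the continuous form

    fc(I) = (sqrt(k^2 + 8 k I - 8 k) - k) / (2 I)   for I >= k.

For ``I <= k`` every infected cell still touches an uninfected one, so
``fc = 1``; a cubic connection polynomial over ``k < I < k + z`` joins
the two branches with a continuous first derivative.  Cultures seeded
with ``psi`` foci growing with irregularity factor ``theta`` use the
effective single-focus size ``I / (psi * theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdjustmentParams",
    "ConnectionCoeffs",
    "ring_fraction",
    "focus_size",
    "fc_ring",
    "fc_ring_deriv",
    "solve_connection",
    "fc_full",
]


def ring_fraction(n: int, k: int = 6):
    """Fraction of CC contributors after completion of expansion ring ``n``.

    Equals perimeter(n) / focus_size(n) = 2kn / (kn^2 + kn + 2); exact for
    integer ``n >= 1`` under radial growth.
    """
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("ring_fraction requires expansion phase n >= 1")
    return 2 * k * n / (k * n**2 + k * n + 2)


def focus_size(n, k: int = 6):
    """Total number of infected cells after completion of ring ``n``.

    ``(k/2) n^2 + (k/2) n + 1``; for k=6 these are the centered-hexagonal
    numbers 1, 7, 19, 37, ...
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("focus_size requires n >= 0")
    return k * n**2 / 2 + k * n / 2 + 1


def fc_ring(I, k: int = 6):
    """Continuous perimeter fraction for focus sizes ``I >= k``.

    Obtained by solving the focus-size relation for ``n`` and substituting
    into the ring fraction; coincides with ``ring_fraction(n, k)`` exactly
    whenever ``I == focus_size(n, k)``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < k):
        raise ValueError("fc_ring is defined for I >= k; use fc_full below k")
    s = np.sqrt(k * k + 8.0 * k * I - 8.0 * k)
    return (s - k) / (2.0 * I)


def fc_ring_deriv(I, k: int = 6):
    """Analytic derivative of ``fc_ring`` with respect to ``I``."""
    I = np.asarray(I, dtype=float)
    s = np.sqrt(k * k + 8.0 * k * I - 8.0 * k)
    return 2.0 * k / (s * I) - (s - k) / (2.0 * I * I)


@dataclass(frozen=True)
class ConnectionCoeffs:
    """Coefficients of the connection cubic f2(I) = a(I-k)^3 + b(I-k)^2 + 1."""

    a: float
    b: float


def solve_connection(k: int, z: float) -> ConnectionCoeffs:
    """Solve for the connection cubic joining ``fc = 1`` to the ring branch.

    The cubic satisfies f2(k) = 1 and f2'(k) = 0 by construction; ``a`` and
    ``b`` are fixed by value and slope matching at ``I = k + z``:

        a z^3 + b z^2 + 1 = fc_ring(k + z)
        3 a z^2 + 2 b z   = fc_ring'(k + z)

    which has the closed-form solution
        a = (F' z - 2 (F - 1)) / z^3,   b = (3 (F - 1) - F' z) / z^2.
    """
    if z <= 0:
        raise ValueError("connection-window width z must be > 0")
    F = float(fc_ring(k + z, k))
    Fp = float(fc_ring_deriv(k + z, k))
    a = (Fp * z - 2.0 * (F - 1.0)) / z**3
    b = (3.0 * (F - 1.0) - Fp * z) / z**2
    return ConnectionCoeffs(a=a, b=b)


@dataclass(frozen=True)
class AdjustmentParams:
    """Parameters of the full adjustment term.

    Attributes
    ----------
    k : neighbors per cell (lattice coordination number, >= 3).
    z : width of the connection window in cells (> 0).
    theta : irregularity scaling; 1 means perfectly circular focus growth.
    psi : number of initially seeded foci.

    The product ``phi = psi * theta`` rescales the total infected-cell
    count to an effective per-focus size before the piecewise map.
    """

    k: int = 6
    z: float = 10.0
    theta: float = 1.0
    psi: float = 1.0
    coeffs: ConnectionCoeffs = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.psi < 1:
            raise ValueError("psi must be >= 1")
        object.__setattr__(self, "coeffs", solve_connection(self.k, self.z))

    @property
    def phi(self) -> float:
        return self.psi * self.theta

    def fc_scalar(self, I: float) -> float:
        """Fast scalar evaluation of fc at total infected count ``I``."""
        x = I / self.phi
        k = self.k
        if x <= k:
            return 1.0
        if x < k + self.z:
            d = x - k
            return self.coeffs.a * d**3 + self.coeffs.b * d**2 + 1.0
        s = math.sqrt(k * k + 8.0 * k * x - 8.0 * k)
        return (s - k) / (2.0 * x)


def fc_full(I, params: AdjustmentParams):
    """Adjustment term fc evaluated at total infected count ``I`` (>= 0).

    Applies the multi-focus/irregularity scaling ``I -> I / (psi*theta)``
    and then the piecewise map: 1 below ``k``, the connection cubic on
    ``(k, k+z)``, and the continuous ring fraction above.  Returns values
    in ``(0, 1]``; vectorized over ``I``.
    """
    I = np.asarray(I, dtype=float)
    scalar = I.ndim == 0
    x = np.atleast_1d(I) / params.phi
    k, z = params.k, params.z
    out = np.ones_like(x)
    mid = (x > k) & (x < k + z)
    if np.any(mid):
        d = x[mid] - k
        out[mid] = params.coeffs.a * d**3 + params.coeffs.b * d**2 + 1.0
    top = x >= k + z
    if np.any(top):
        out[top] = fc_ring(x[top], k)
    return float(out[0]) if scalar else out
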