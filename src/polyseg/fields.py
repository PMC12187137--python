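"""Field state and finite-difference operators on the rescaled domain.

The simulation lives on the unit interval x̃ = x / L(t) with a cell-centred
grid of N points, x̃_i = (i + 1/2)/N.  No-flux boundaries are realised with
reflective ghost points (zero-gradient), which makes the conservative
divergence/gradient pair below telescope exactly: the discrete integral
h·Σu of a transported field is conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["FieldState", "grid_centers", "lap", "div_flux", "integrate"]

EPS_CLIP = 1e-6  # fraction clipping band for the logarithms


def grid_centers(N: int) -> np.ndarray:
    """Cell-centred rescaled coordinates x̃_i = (i+1/2)/N."""
    return (np.arange(N) + 0.5) / N


def lap(u: np.ndarray, h: float) -> np.ndarray:
    """Neumann (zero-gradient) Laplacian ∂²u/∂x̃² on the cell-centred grid."""
    out = np.empty_like(u)
    out[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2])
    out[0] = u[1] - u[0]
    out[-1] = u[-2] - u[-1]
    out /= h * h
    return out


def div_flux(mobility: np.ndarray, potential: np.ndarray, h: float) -> np.ndarray:
    """Conservative transport term ∂x̃(M ∂x̃ μ) with zero boundary flux.

    Interface mobilities are arithmetic means of the adjacent cells; the
    boundary fluxes are identically zero, so h·Σ of the result vanishes.
    """
    m_face = 0.5 * (mobility[1:] + mobility[:-1])
    flux = m_face * (potential[1:] - potential[:-1]) / h  # at interior faces
    out = np.empty_like(potential)
    out[1:-1] = flux[1:] - flux[:-1]
    out[0] = flux[0]
    out[-1] = -flux[-1]
    out /= h
    return out


def integrate(u: np.ndarray) -> float:
    """∫ u dx̃ over the unit rescaled domain (midpoint rule)."""
    return float(np.sum(u) / u.size)


@dataclass
class FieldState:
    """Volume-fraction fields of the mixture at one instant.

    ``p`` and ``n`` are the polysome and nucleoid volume fractions on the
    rescaled domain (length-N arrays), ``L`` the current cell length in μm
    and ``t`` the elapsed model time in s.  ``p_species`` optionally carries
    the species-resolved polysome fields (k × N), which sum to ``p``.

    The fields are oriented so that, after a division, the new pole sits at
    x̃ = 1 and the old pole at x̃ = 0.
    """

    p: np.ndarray
    n: np.ndarray
    L: float
    t: float = 0.0
    p_species: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.p.shape != self.n.shape or self.p.ndim != 1:
            raise ValueError("p and n must be 1D arrays of identical length")
        if not self.L > 0:
            raise ValueError("cell length must be positive")

    @property
    def N(self) -> int:
        return self.p.size

    def validate(self) -> None:
        """Raise if the volume-fraction invariants are violated."""
        if not (np.all(np.isfinite(self.p)) and np.all(np.isfinite(self.n))):
            raise ValueError("non-finite field values")
        if np.any(self.p <= 0) or np.any(self.n <= 0):
            raise ValueError("volume fractions must be strictly positive")
        if np.any(self.p + self.n >= 1.0):
            raise ValueError("p + n must stay below 1 (three-component mixture)")

    def copy(self) -> "FieldState":
        return FieldState(self.p.copy(), self.n.copy(), self.L, self.t,
                          None if self.p_species is None else self.p_species.copy())

    def flipped(self) -> "FieldState":
        """State mirrored about mid-domain (pole labels exchanged)."""
        return FieldState(self.p[::-1].copy(), self.n[::-1].copy(), self.L, self.t,
                          None if self.p_species is None else self.p_species[:, ::-1].copy())
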