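"""Flory–Huggins free energy, chemical potentials and mobilities.

The non-dimensionalised free-energy density of the ternary mixture of
nucleoid (volume fraction n), polysomes (p) and remaining cytosol
(s = 1 − p − n) is

    f(n, p) = p/v_p ln p + n/v_n ln n + s ln s
              + χ_p p s + χ_n n s + χ_np n p
              − κ_p ∇p·∇s − κ_n ∇n·∇s − κ_np ∇n·∇p,

with κ_ij = λ² χ_ij.  The chemical potentials μ = δF/δ(field) evaluate, in
rescaled coordinates with λ̃ = λ/L(t), to

    μ_p = v_p⁻¹ ln p − ln s + χ_p (1 − 2p − n) + (χ_np − χ_n) n
          − χ_p λ̃² ∂²x̃ (2p + n) + (χ_np − χ_n) λ̃² ∂²x̃ n,

and symmetrically for μ_n.  (As is conventional, additive constants from
the entropy terms are dropped; only ∇μ enters the dynamics.)

Mobilities are M_p = v_p D_p p and M_n = v_n D_n n, rescaled on the unit
domain as M̃ = M / L(t)².
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np

from .fields import EPS_CLIP, FieldState, integrate, lap
from .params import FloryHugginsParams, KineticParams

__all__ = [
    "free_energy_density",
    "chemical_potentials",
    "mobilities",
    "total_free_energy",
]

ArrayLike = Union[float, np.ndarray]


def _clipped_log(u: ArrayLike) -> ArrayLike:
    return np.log(np.clip(u, EPS_CLIP, 1.0 - EPS_CLIP))


def _check_fractions(n: ArrayLike, p: ArrayLike) -> None:
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(n <= 0) or np.any(p <= 0) or np.any(n + p >= 1):
        raise ValueError("volume fractions must satisfy 0 < n, 0 < p, n + p < 1")


def free_energy_density(n: ArrayLike, p: ArrayLike,
                        grad_n: ArrayLike, grad_p: ArrayLike,
                        params: FloryHugginsParams) -> ArrayLike:
    """Local free-energy density f(n, p, ∇n, ∇p) (dimensionless).

    Gradients are per μm (physical coordinates).  Raises ``ValueError``
    when a fraction leaves (0, 1) or n + p ≥ 1, where the entropy
    logarithms are undefined.
    """
    _check_fractions(n, p)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    s = 1.0 - p - n
    grad_s = -(np.asarray(grad_n, dtype=float) + np.asarray(grad_p, dtype=float))
    local = (p / params.v_p * np.log(p)
             + n / params.v_n * np.log(n)
             + s * np.log(s)
             + params.chi_p * p * s
             + params.chi_n * n * s
             + params.chi_np * n * p)
    gradient = (-params.kappa_p * grad_p * grad_s
                - params.kappa_n * grad_n * grad_s
                - params.kappa_np * grad_n * grad_p)
    out = local + gradient
    return float(out) if np.ndim(out) == 0 else out


def chemical_potentials(state: FieldState, params: FloryHugginsParams,
                        kinetics: KineticParams | None = None,
                        validate: bool = True,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Chemical potentials (μ_p, μ_n) on the rescaled grid.

    Second derivatives are taken in rescaled coordinates with reflective
    (zero-gradient) ghost points, consistent with no-flux boundaries.
    ``kinetics`` is accepted for interface symmetry but unused: the
    potentials depend only on the thermodynamic parameters.
    """
    if validate:
        state.validate()
    p, n = state.p, state.n
    s = 1.0 - p - n
    h = 1.0 / state.N
    lam2 = (params.lambda_if / state.L) ** 2
    lap_p = lap(p, h)
    lap_n = lap(n, h)
    log_s = _clipped_log(s)
    mu_p = (np.log(np.clip(p, EPS_CLIP, None)) / params.v_p - log_s
            + params.chi_p * (1.0 - 2.0 * p - n)
            + (params.chi_np - params.chi_n) * n
            - params.chi_p * lam2 * (2.0 * lap_p + lap_n)
            + (params.chi_np - params.chi_n) * lam2 * lap_n)
    mu_n = (np.log(np.clip(n, EPS_CLIP, None)) / params.v_n - log_s
            + params.chi_n * (1.0 - 2.0 * n - p)
            + (params.chi_np - params.chi_p) * p
            - params.chi_n * lam2 * (2.0 * lap_n + lap_p)
            + (params.chi_np - params.chi_p) * lam2 * lap_p)
    return mu_p, mu_n


def mobilities(state: FieldState, kinetics: KineticParams,
               fh: FloryHugginsParams, validate: bool = True,
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Rescaled mobilities (M̃_p, M̃_n) = (v_p D_p p, v_n D_n n) / L²."""
    if validate:
        state.validate()
    L2 = state.L * state.L
    m_p = fh.v_p * kinetics.D_p * state.p / L2
    m_n = fh.v_n * kinetics.D_n * state.n / L2
    return m_p, m_n


def total_free_energy(state: FieldState, params: FloryHugginsParams) -> float:
    """Discrete total free energy F = ∫ f dx̃ on the rescaled domain.

    Gradient contributions are accumulated on cell interfaces with the same
    stencil the chemical potentials discretise, so this F is the exact
    discrete Lyapunov functional of the transport dynamics.
    """
    p, n = state.p, state.n
    s = 1.0 - p - n
    h = 1.0 / state.N
    lam2 = (params.lambda_if / state.L) ** 2
    local = (p / params.v_p * _clipped_log(p)
             + n / params.v_n * _clipped_log(n)
             + s * _clipped_log(s))
    local += (params.chi_p * p * s + params.chi_n * n * s + params.chi_np * n * p)
    F = integrate(local)
    # interface gradients in rescaled coordinates (zero at the boundaries)
    dp = (p[1:] - p[:-1]) / h
    dn = (n[1:] - n[:-1]) / h
    ds = -(dp + dn)
    grad_sum = np.sum(-params.chi_p * dp * ds
                      - params.chi_n * dn * ds
                      - params.chi_np * dn * dp)
    F += lam2 * grad_sum * h
    return float(F)
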