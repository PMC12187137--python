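"""Parameter containers for the polysome–nucleoid phase-separation model.

Units are μm and seconds internally.  Growth rates are commonly quoted in
h⁻¹ in the bacterial-physiology literature; :class:`GrowthSpec` accepts h⁻¹
at the configuration boundary and converts once (``gamma_per_s``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FloryHugginsParams",
    "KineticParams",
    "GrowthSpec",
    "GridSpec",
    "EctopicSource",
    "ModelConfig",
    "birth_length",
    "SWEEP_GROWTH_RATES_PER_H",
]

#: the ten growth rates of the standard growth-rate sweep, h^-1
SWEEP_GROWTH_RATES_PER_H = (0.25, 0.36, 0.46, 0.57, 0.67, 0.78, 0.88, 0.99, 1.09, 1.2)

#: birth-length regression L(0) = l0 * exp(gamma / gamma0)
BIRTH_LENGTH_L0_UM = 2.00
BIRTH_LENGTH_GAMMA0_PER_H = 2.81


def birth_length(gamma_per_hour: float, l0: float = BIRTH_LENGTH_L0_UM,
                 gamma0: float = BIRTH_LENGTH_GAMMA0_PER_H) -> float:
    """Cell length at birth (μm) for a given growth rate (h⁻¹).

    Uses the empirical exponential relation ``L(0) = l0 * exp(gamma/gamma0)``
    that matches population-averaged newborn lengths across growth rates.
    """
    return float(l0 * np.exp(gamma_per_hour / gamma0))


@dataclass(frozen=True)
class FloryHugginsParams:
    """Flory–Huggins interaction and interface parameters.

    The free-energy density of the ternary (nucleoid / polysome / cytosol)
    regular solution is parameterised by three dimensionless interaction
    parameters ``chi_p`` (polysome–solvent), ``chi_n`` (nucleoid–solvent) and
    ``chi_np`` (nucleoid–polysome), molecular volume factors ``v_p``/``v_n``
    of the elementary translational degrees of freedom, and a characteristic
    interface width ``lambda_if`` (μm).  Interfacial tensions are derived as
    ``kappa_ij = lambda_if**2 * chi_ij``.
    """

    chi_p: float = 0.2
    chi_n: float = 0.4
    chi_np: float = 1.2
    lambda_if: float = 0.03  # μm
    v_p: float = 5.0
    v_n: float = 10.0

    def __post_init__(self) -> None:
        for name in ("chi_p", "chi_n", "chi_np", "lambda_if", "v_p", "v_n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"FloryHugginsParams.{name} must be strictly positive")

    # interfacial tensions, μm²  (exact identities, never stored separately)
    @property
    def kappa_p(self) -> float:
        return self.lambda_if**2 * self.chi_p

    @property
    def kappa_n(self) -> float:
        return self.lambda_if**2 * self.chi_n

    @property
    def kappa_np(self) -> float:
        return self.lambda_if**2 * self.chi_np

    def swapped(self) -> "FloryHugginsParams":
        """Parameters with the nucleoid/polysome labels exchanged."""
        return FloryHugginsParams(chi_p=self.chi_n, chi_n=self.chi_p,
                                  chi_np=self.chi_np, lambda_if=self.lambda_if,
                                  v_p=self.v_n, v_n=self.v_p)


@dataclass(frozen=True)
class KineticParams:
    """Diffusion and polysome production/degradation rates.

    ``D_p``/``D_n`` are the polysome and nucleoid diffusion coefficients
    (μm²/s); ``k1_0`` is the baseline polysome production rate inside the
    nucleoid (s⁻¹) and ``k_deg`` the uniform degradation rate (s⁻¹).  The
    effective production rate grows with the growth rate γ as
    ``k1 = k1_0 * (1 + γ / k_deg)`` so that nucleoid length stays
    proportional to cell length.
    """

    D_p: float = 0.023
    D_n: float = 0.001
    k1_0: float = 0.002
    k_deg: float = 0.003

    def __post_init__(self) -> None:
        if not (self.D_p > 0 and self.D_n > 0):
            raise ValueError("diffusion coefficients must be positive")
        if self.k1_0 < 0:
            raise ValueError("k1_0 must be non-negative")
        if not self.k_deg > 0:
            raise ValueError("k_deg must be positive")

    def k1(self, gamma_per_s: float) -> float:
        """Growth-rate-compensated polysome production rate (s⁻¹)."""
        return self.k1_0 * (1.0 + gamma_per_s / self.k_deg)


@dataclass(frozen=True)
class GrowthSpec:
    """Exponential growth law L(t) = L0 * exp(gamma*t).

    ``gamma`` is given in h⁻¹ (the unit used at the configuration boundary);
    ``L0`` in μm.  If ``L0`` is omitted it is derived from the birth-length
    regression.
    """

    gamma: float = 0.0           # h^-1
    L0: Optional[float] = None   # μm

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("growth rate must be non-negative")
        if self.L0 is None:
            object.__setattr__(self, "L0", birth_length(self.gamma))
        if not self.L0 > 0:
            raise ValueError("birth length must be positive")

    @property
    def gamma_per_s(self) -> float:
        return self.gamma / 3600.0

    @property
    def doubling_time_s(self) -> float:
        if self.gamma == 0:
            return np.inf
        return float(np.log(2.0) / self.gamma_per_s)


@dataclass(frozen=True)
class GridSpec:
    """Spatial/temporal discretisation of the rescaled unit domain."""

    N: int = 128
    dt: float = 0.05        # s
    sample_stride: int = 200  # record every `stride` steps in trajectories

    def __post_init__(self) -> None:
        if self.N < 16:
            raise ValueError("need at least 16 grid points")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass(frozen=True)
class EctopicSource:
    """Ectopic (nucleoid-independent) polysome production window.

    ``kind`` selects a window at one pole (``polar``), centred at mid-cell
    (``midcell``) or no source (``none``).  ``amplitude`` is a multiple of
    the current k1; ``extent`` is the window size in μm measured from the
    pole (polar) or from mid-cell (midcell).  ``k1_reduction`` multiplies
    the nucleoid-templated production rate (k1' = k1_reduction * k1) while
    the source is active.
    """

    kind: str = "none"          # {"none", "polar", "midcell"}
    amplitude: float = 0.0      # multiple of k1
    extent: float = 0.0         # μm
    k1_reduction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "polar", "midcell"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("source amplitude must be non-negative")
        if self.kind != "none" and not self.extent > 0:
            raise ValueError("source extent must be positive")
        if not 0.0 <= self.k1_reduction <= 1.0:
            raise ValueError("k1_reduction must lie in [0, 1]")


@dataclass(frozen=True)
class ModelConfig:
    """Complete specification of one simulation."""

    fh: FloryHugginsParams = field(default_factory=FloryHugginsParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    source: EctopicSource = field(default_factory=EctopicSource)
    #: per-species polysome diffusion coefficients (μm²/s) for the
    #: multi-species extension; None for the single-species model
    D_p_species: Optional[Sequence[float]] = None
    seed: int = 0

    def with_growth(self, gamma_per_hour: float, L0: Optional[float] = None) -> "ModelConfig":
        return replace(self, growth=GrowthSpec(gamma=gamma_per_hour, L0=L0))

    @property
    def k1(self) -> float:
        """Effective polysome production rate for this growth rate (s⁻¹)."""
        return self.kinetics.k1(self.growth.gamma_per_s)
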