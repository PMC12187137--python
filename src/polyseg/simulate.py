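"""Time integration of the rescaled polysome–nucleoid dynamics.

The volume fractions evolve on the fixed unit domain x̃ = x/L(t) as

    ∂p/∂t = ∂x̃(M̃_p ∂x̃ μ_p) + k1 n − (k_-1 + γ) p   [+ ectopic source]
    ∂n/∂t = ∂x̃(M̃_n ∂x̃ μ_n)

with exponential length growth L(t) = L(0) e^{γt} and no-flux boundaries.

Time stepping uses a linearised implicit–explicit (IMEX) scheme.  The stiff
own-field part of each transport operator — the fourth-derivative interface
term and the quasi-linear second-derivative term, both with mobilities and
local free-energy curvature frozen at the current state — is treated
implicitly; the cross-field couplings and the reaction terms are explicit.
Writing J for the frozen own-field Jacobian of ∂x̃(M̃ ∂x̃ μ),

    (I − Δt J) u^{m+1} = u^m + Δt [ N(u^m) − J u^m ],

i.e. u^{m+1} = u^m + (I − Δt J)^{-1} Δt N(u^m): a Rosenbrock-type backward
Euler step that leaves fixed points of the dynamics exactly invariant and
conserves the discrete integral of a transported field to round-off (all
operators are in conservative flux form with zero boundary fluxes, so their
columns telescope).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg.lapack import dgbsv as _dgbsv

from .energy import chemical_potentials, mobilities
from .fields import EPS_CLIP, FieldState, div_flux, grid_centers, integrate, lap
from .params import ModelConfig

__all__ = [
    "SimulationInstabilityError",
    "ConvergenceError",
    "Trajectory",
    "Stepper",
    "reaction_terms",
    "step",
    "relax_to_steady_state",
    "simulate_generation",
    "divide",
    "simulate_multispecies",
    "spread_nucleoid_state",
    "compact_nucleoid_state",
    "initial_steady_state",
]

_INSTABILITY_BAND = 1e-3  # how far past (0,1) a field may stray before aborting
_MAX_DT_HALVINGS = 4


class SimulationInstabilityError(RuntimeError):
    """A field became non-finite or left (0,1) beyond the clipping band."""


class ConvergenceError(RuntimeError):
    """relax_to_steady_state hit its time budget before reaching tolerance."""


# ---------------------------------------------------------------------------
# initial conditions

def spread_nucleoid_state(config: ModelConfig, n_mean: float = 0.30,
                          sigma: float = 0.30) -> FieldState:
    """State with the nucleoid spread throughout most of the cell.

    The nucleoid is a broad Gaussian centred at mid-cell (``sigma`` in units
    of cell length) reaching the poles with a small but nonzero density; the
    polysomes are homogeneous at the production–degradation balance value
    p = k1 n̄ / (k_-1 + γ).  A centrally-peaked spread compacts directly
    into a single mid-cell nucleoid; a flat plateau would instead fragment
    by spinodal decomposition into several blobs that coarsen extremely
    slowly.
    """
    N = config.grid.N
    x = grid_centers(N)
    bump = np.exp(-0.5 * ((x - 0.5) / sigma) ** 2) + EPS_CLIP
    n = bump * (n_mean / integrate(bump))
    gamma = config.growth.gamma_per_s
    p_bal = config.k1 * n_mean / (config.kinetics.k_deg + gamma)
    return FieldState(p=np.full(N, p_bal), n=n, L=config.growth.L0, t=0.0)


def compact_nucleoid_state(config: ModelConfig, n_mean: float = 0.30,
                           width: float = 0.15) -> FieldState:
    """Gaussian-bump nucleoid at mid-domain (pre-relaxation seed)."""
    N = config.grid.N
    x = grid_centers(N)
    bump = np.exp(-0.5 * ((x - 0.5) / width) ** 2) + EPS_CLIP
    n = np.clip(bump * (n_mean / integrate(bump)), EPS_CLIP, 0.9)
    gamma = config.growth.gamma_per_s
    p_bal = config.k1 * n_mean / (config.kinetics.k_deg + gamma)
    return FieldState(p=np.full(N, p_bal), n=n, L=config.growth.L0, t=0.0)


# ---------------------------------------------------------------------------
# reaction terms

def ectopic_rate(config: ModelConfig, L: float) -> np.ndarray:
    """Ectopic production rate k_ect(x̃) (s⁻¹) on the grid at length L."""
    N = config.grid.N
    x_um = grid_centers(N) * L
    src = config.source
    if src.kind == "none" or src.amplitude == 0.0:
        return np.zeros(N)
    if src.kind == "polar":
        window = x_um < src.extent
    else:  # midcell
        window = np.abs(x_um - 0.5 * L) < src.extent
    return np.where(window, src.amplitude * config.k1, 0.0)


def reaction_terms(state: FieldState, config: ModelConfig,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Reaction contributions (dp, dn) in s⁻¹.

    Polysomes are produced inside the nucleoid at rate k1 (reduced to
    k1' = k1_reduction·k1 when an ectopic source is active), degraded
    uniformly at k_-1 and diluted by growth at γ; the nucleoid has no
    reaction term.
    """
    gamma = config.growth.gamma_per_s
    k1 = config.k1
    if config.source.kind != "none":
        k1 = config.source.k1_reduction * k1
    dp = k1 * state.n - (config.kinetics.k_deg + gamma) * state.p
    if config.source.kind != "none":
        dp = dp + ectopic_rate(config, state.L)
    return dp, np.zeros_like(state.n)


# ---------------------------------------------------------------------------
# the stepper

class Stepper:
    """Caches the grid operators for repeated stepping of one config.

    ``freeze_length`` integrates the dynamics at fixed cell length while
    keeping the growth rate's contribution to the reaction terms — the
    regime used for steady-state relaxations.
    """

    def __init__(self, config: ModelConfig, dt: Optional[float] = None,
                 freeze_length: bool = False):
        self.config = config
        self.freeze_length = freeze_length
        self.N = config.grid.N
        self.h = 1.0 / self.N
        self.dt = config.grid.dt if dt is None else dt
        N, h = self.N, self.h
        # Neumann Laplacian bands (cell-centred, conservative)
        self._d2_diag = np.full(N, -2.0) / h**2
        self._d2_diag[0] = self._d2_diag[-1] = -1.0 / h**2
        self._d2_off = np.full(N - 1, 1.0) / h**2

    def _jacobian_bands(self, m_face: np.ndarray, fpp: np.ndarray, c_if: float,
                        ) -> Tuple[np.ndarray, ...]:
        """Pentadiagonal bands of J = A_M∘diag(f'') − c_if·A_M @ D2.

        ``A_M`` is the conservative variable-coefficient diffusion operator
        v ↦ ∂x̃(M ∂x̃ v) with face mobilities ``m_face`` (length N−1) and
        zero boundary fluxes; ``fpp`` the local curvature ∂μ_alg/∂u at the
        nodes; ``c_if`` the interface coefficient 2 χ λ̃².
        Returns (lo2, lo1, diag, up1, up2) as full-length arrays (padded).
        """
        N, h = self.N, self.h
        mf = np.zeros(N + 1)
        mf[1:-1] = m_face  # mf[i] = face between cells i-1 and i
        inv_h2 = 1.0 / h**2
        # A_M bands: aL[i] = A[i,i-1], aD[i] = A[i,i], aU[i] = A[i,i+1]
        aL = mf[:-1] * inv_h2
        aU = mf[1:] * inv_h2
        aD = -(mf[:-1] + mf[1:]) * inv_h2
        # J2 = A_M @ diag(fpp): column scaling
        j2_lo1 = aL[1:] * fpp[:-1]
        j2_diag = aD * fpp
        j2_up1 = aU[:-1] * fpp[1:]
        # D2 bands
        dD = self._d2_diag
        dO = self._d2_off  # constant 1/h², both sub and super
        # P = A_M @ D2 (pentadiagonal)
        p_lo2 = aL[2:] * dO[:-1]                      # P[i,i-2], i>=2
        p_lo1 = aL[1:] * dD[:-1] + aD[1:] * dO        # P[i,i-1], i>=1
        p_diag = np.empty(N)
        p_diag[:] = aD * dD
        p_diag[1:] += aL[1:] * dO
        p_diag[:-1] += aU[:-1] * dO
        p_up1 = aD[:-1] * dO + aU[:-1] * dD[1:]       # P[i,i+1]
        p_up2 = aU[:-2] * dO[1:]                      # P[i,i+2]
        lo2 = -c_if * p_lo2
        lo1 = j2_lo1 - c_if * p_lo1
        diag = j2_diag - c_if * p_diag
        up1 = j2_up1 - c_if * p_up1
        up2 = -c_if * p_up2
        return lo2, lo1, diag, up1, up2

    def _implicit_solve(self, rhs: np.ndarray, bands: Tuple[np.ndarray, ...],
                        ) -> np.ndarray:
        """Solve (I − dt·J) u = rhs for pentadiagonal J given by bands."""
        lo2, lo1, diag, up1, up2 = bands
        dt = self.dt
        N = self.N
        # LAPACK general-banded storage: 2 extra rows of workspace for dgbsv
        ab = np.zeros((7, N))
        ab[2, 2:] = -dt * up2
        ab[3, 1:] = -dt * up1
        ab[4, :] = 1.0 - dt * diag
        ab[5, :-1] = -dt * lo1
        ab[6, :-2] = -dt * lo2
        _, _, x, info = _dgbsv(2, 2, ab, rhs, overwrite_ab=True, overwrite_b=False)
        if info != 0:
            raise SimulationInstabilityError(f"implicit banded solve failed (info={info})")
        return x

    @staticmethod
    def _apply_bands(bands: Tuple[np.ndarray, ...], u: np.ndarray) -> np.ndarray:
        lo2, lo1, diag, up1, up2 = bands
        out = diag * u
        out[1:] += lo1 * u[:-1]
        out[:-1] += up1 * u[1:]
        out[2:] += lo2 * u[:-2]
        out[:-2] += up2 * u[2:]
        return out

    def _clip_or_raise(self, u: np.ndarray, label: str) -> np.ndarray:
        if not np.all(np.isfinite(u)):
            raise SimulationInstabilityError(f"non-finite {label} field")
        if np.any(u < -_INSTABILITY_BAND) or np.any(u > 1.0 + _INSTABILITY_BAND):
            raise SimulationInstabilityError(
                f"{label} field left (0,1) beyond the clipping band")
        return np.clip(u, EPS_CLIP, 1.0 - EPS_CLIP)

    def _grow(self, L: float) -> float:
        if self.freeze_length:
            return L
        return L * float(np.exp(self.config.growth.gamma_per_s * self.dt))

    def advance(self, state: FieldState) -> FieldState:
        """One IMEX step; advances t by dt and L by the growth factor."""
        cfg = self.config
        fh = cfg.fh
        mu_p, mu_n = chemical_potentials(state, fh, validate=False)
        m_p, m_n = mobilities(state, cfg.kinetics, fh, validate=False)
        dp_rx, _ = reaction_terms(state, cfg)
        rhs_p_expl = div_flux(m_p, mu_p, self.h) + dp_rx
        rhs_n_expl = div_flux(m_n, mu_n, self.h)
        # frozen own-field Jacobians (fractions clipped so the entropy
        # curvature stays finite when a field grazes zero)
        s = np.clip(1.0 - state.p - state.n, EPS_CLIP, None)
        lam2 = (fh.lambda_if / state.L) ** 2
        fpp = (1.0 / (fh.v_p * np.clip(state.p, EPS_CLIP, None))
               + 1.0 / s - 2.0 * fh.chi_p)
        fnn = (1.0 / (fh.v_n * np.clip(state.n, EPS_CLIP, None))
               + 1.0 / s - 2.0 * fh.chi_n)
        bands_p = self._jacobian_bands(0.5 * (m_p[1:] + m_p[:-1]), fpp,
                                       2.0 * fh.chi_p * lam2)
        bands_n = self._jacobian_bands(0.5 * (m_n[1:] + m_n[:-1]), fnn,
                                       2.0 * fh.chi_n * lam2)
        dt = self.dt
        rhs_p = state.p + dt * rhs_p_expl - dt * self._apply_bands(bands_p, state.p)
        rhs_n = state.n + dt * rhs_n_expl - dt * self._apply_bands(bands_n, state.n)
        p_new = self._implicit_solve(rhs_p, bands_p)
        n_new = self._implicit_solve(rhs_n, bands_n)
        p_new = self._clip_or_raise(p_new, "polysome")
        n_new = self._clip_or_raise(n_new, "nucleoid")
        tot = p_new + n_new
        over = tot >= 1.0 - EPS_CLIP
        if np.any(over):  # keep the solvent fraction positive
            scale = (1.0 - 2.0 * EPS_CLIP) / tot[over]
            p_new[over] *= scale
            n_new[over] *= scale
        return FieldState(p=p_new, n=n_new, L=self._grow(state.L), t=state.t + dt)


def step(state: FieldState, config: ModelConfig) -> FieldState:
    """Advance the state by one time step (convenience wrapper)."""
    return Stepper(config).advance(state)


# ---------------------------------------------------------------------------
# trajectory container

@dataclass
class Trajectory:
    """Time-ordered samples of a simulation (rescaled fields + length)."""

    times: np.ndarray          # s
    lengths: np.ndarray        # μm
    p: np.ndarray              # (T, N)
    n: np.ndarray              # (T, N)
    species: Optional[np.ndarray] = None  # (T, k, N)

    def __len__(self) -> int:
        return int(self.times.size)

    def state(self, i: int) -> FieldState:
        sp = None if self.species is None else self.species[i].copy()
        return FieldState(p=self.p[i].copy(), n=self.n[i].copy(),
                          L=float(self.lengths[i]), t=float(self.times[i]),
                          p_species=sp)

    @property
    def final_state(self) -> FieldState:
        return self.state(len(self) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, position, species, value)."""
        N = self.p.shape[1]
        x = grid_centers(N)
        blocks = []
        mats = [("polysome", self.p), ("nucleoid", self.n)]
        if self.species is not None:
            mats += [(f"polysome_{k}", self.species[:, k, :])
                     for k in range(self.species.shape[1])]
        for label, mat in mats:
            blocks.append(pd.DataFrame({
                "time_s": np.repeat(self.times, N),
                "length_um": np.repeat(self.lengths, N),
                "position": np.tile(x, len(self)),
                "species": label,
                "value": np.asarray(mat).reshape(-1),
            }))
        return pd.concat(blocks, ignore_index=True)


class _Recorder:
    def __init__(self, with_species: bool = False):
        self.times: List[float] = []
        self.lengths: List[float] = []
        self.ps: List[np.ndarray] = []
        self.ns: List[np.ndarray] = []
        self.sps: List[np.ndarray] = []
        self.with_species = with_species

    def record(self, state: FieldState) -> None:
        self.times.append(state.t)
        self.lengths.append(state.L)
        self.ps.append(state.p.copy())
        self.ns.append(state.n.copy())
        if self.with_species:
            self.sps.append(state.p_species.copy())

    def build(self) -> Trajectory:
        return Trajectory(
            times=np.asarray(self.times), lengths=np.asarray(self.lengths),
            p=np.asarray(self.ps), n=np.asarray(self.ns),
            species=np.asarray(self.sps) if self.with_species else None)


# ---------------------------------------------------------------------------
# drivers (with automatic dt halving on instability)

def _retrying(func):
    def wrapper(config: ModelConfig, *args, **kwargs):
        dt = config.grid.dt
        last_err: Optional[Exception] = None
        for _ in range(_MAX_DT_HALVINGS + 1):
            try:
                return func(replace(config, grid=replace(config.grid, dt=dt)),
                            *args, **kwargs)
            except SimulationInstabilityError as err:
                last_err = err
                dt *= 0.5
        raise SimulationInstabilityError(
            f"unstable even after {_MAX_DT_HALVINGS} dt halvings") from last_err
    wrapper.__name__ = func.__name__
    wrapper.__doc__ = func.__doc__
    return wrapper


@_retrying
def relax_to_steady_state(config: ModelConfig, init: FieldState,
                          tol: float = 1e-8, max_time: float = 4e4,
                          ) -> Tuple[FieldState, float]:
    """Integrate at fixed cell length until max|Δfield|/Δt < tol (s⁻¹).

    The length is frozen at ``init.L``; the configured growth rate still
    enters the reaction rates (production boost and dilution), so for γ > 0
    the result is the nonequilibrium steady state the growing cell would
    track at that length, and for γ = 0 the plain fixed-length steady
    state.  Returns the final state and the elapsed model time; raises
    :class:`ConvergenceError` after ``max_time`` seconds of model time.
    """
    stepper = Stepper(config, freeze_length=True)
    state = init.copy()
    t0 = state.t
    dt = stepper.dt
    while state.t - t0 < max_time:
        new = stepper.advance(state)
        rate = max(float(np.max(np.abs(new.p - state.p))),
                   float(np.max(np.abs(new.n - state.n)))) / dt
        state = new
        if rate < tol:
            return state, state.t - t0
    raise ConvergenceError(
        f"no steady state within {max_time} s of model time (tol={tol})")


@_retrying
def simulate_generation(config: ModelConfig, init: FieldState) -> Trajectory:
    """Integrate one cell cycle: from birth length L0 until L = 2·L0.

    States are recorded every ``grid.sample_stride`` steps plus the final
    (predivisional) state.  With γ = 0 this degenerates to a fixed-length
    relaxation capped at a configured step budget.
    """
    stepper = Stepper(config)
    state = init.copy()
    L_target = 2.0 * init.L
    rec = _Recorder()
    rec.record(state)
    stride = config.grid.sample_stride
    gamma = config.growth.gamma_per_s
    if gamma > 0:
        max_steps = int(np.ceil(np.log(2.0) / gamma / stepper.dt)) + 2
    else:
        max_steps = int(np.ceil(4e4 / stepper.dt))
    i = 0
    while state.L < L_target and i < max_steps:
        state = stepper.advance(state)
        i += 1
        if i % stride == 0:
            rec.record(state)
    if i % stride != 0:
        rec.record(state)
    return rec.build()


def divide(predivisional: FieldState, config: ModelConfig,
           daughter: str = "old_pole") -> Tuple[FieldState, str]:
    """Split the predivisional cell at mid-domain and return one daughter.

    ``daughter`` selects which half to keep: ``"old_pole"`` keeps the half
    containing the mother's old pole (x̃ < 1/2), ``"new_pole"`` the other
    half.  The kept half is resampled onto the full N grid points by
    integral-conserving linear interpolation, the length halved, and the
    fields oriented with the daughter's new pole — the former division
    plane — at x̃ = 1 (so the old-pole daughter keeps its orientation and
    the new-pole daughter is mirrored).  Returns the daughter state and the
    side of its new pole ("right" by construction).
    """
    if daughter not in ("old_pole", "new_pole"):
        raise ValueError("daughter must be 'old_pole' or 'new_pole'")
    N = predivisional.N
    x_old = grid_centers(N)
    x_new = grid_centers(N)  # daughter coordinates

    def _resample(u: np.ndarray) -> np.ndarray:
        if daughter == "old_pole":
            # daughter ξ ∈ [0,1] maps to mother x̃ = ξ/2
            v = np.interp(0.5 * x_new, x_old, u)
            target = float(np.mean(u[: N // 2]))
        else:
            # daughter ξ maps to mother x̃ = 1 − ξ/2 (mirrored right half)
            v = np.interp(1.0 - 0.5 * x_new, x_old, u)
            target = float(np.mean(u[N // 2:]))
        cur = float(np.mean(v))
        if cur > 0:
            v = v * (target / cur)
        if abs(float(np.mean(v)) - target) > 1e-6 * max(abs(target), 1e-30):
            raise SimulationInstabilityError(
                "division resampling failed to conserve the field integral")
        return v

    state = FieldState(p=_resample(predivisional.p), n=_resample(predivisional.n),
                       L=predivisional.L / 2.0, t=predivisional.t)
    return state, "right"


def initial_steady_state(config: ModelConfig, tol: float = 1e-8,
                         n_mean: float = 0.30) -> FieldState:
    """First-generation initial condition: the symmetric steady state at L0.

    Obtained by relaxing a compact mid-domain Gaussian-bump nucleoid at
    fixed length L0 under the growth rate's reaction rates.
    """
    seed = compact_nucleoid_state(config, n_mean=n_mean)
    state, _ = relax_to_steady_state(config, seed, tol=tol)
    state.t = 0.0
    return state


# ---------------------------------------------------------------------------
# multi-species extension

def _coupled_species_solve(bands_by_species, rhs: np.ndarray, dt: float,
                           k: int, N: int, own_bands=None) -> np.ndarray:
    """Solve (I − dt·J) u = rhs for k coupled species fields.

    Unknowns are interleaved grid-major (u[i*k + j] = species j at cell i).
    ``bands_by_species[j]`` is the part of species j's Jacobian that acts on
    every species column (the interaction/interfacial terms depend on total
    p); ``own_bands[j]``, if given, acts on species j's own column only (the
    per-species entropy term).  Bandwidth kl = ku = 3k − 1.
    """
    kn = k * N
    kl = ku = 3 * k - 1
    ab = np.zeros((2 * kl + ku + 1, kn))
    row0 = kl + ku  # ab[row0 + g - g2, g2] = A[g, g2]
    i_idx = np.arange(N)
    for j, bands in enumerate(bands_by_species):
        lo2, lo1, diag, up1, up2 = bands
        for b, vals, i_lo in ((-2, lo2, 2), (-1, lo1, 1), (0, diag, 0),
                              (1, up1, 0), (2, up2, 0)):
            v = np.asarray(vals)
            n_entries = v.size
            ii = i_idx[i_lo:i_lo + n_entries]
            for m in range(k):
                g = ii * k + j
                g2 = (ii + b) * k + m
                ab[row0 + g - g2, g2] += -dt * v
    if own_bands is not None:
        for j, bands in enumerate(own_bands):
            lo2, lo1, diag, up1, up2 = bands
            for b, vals, i_lo in ((-2, lo2, 2), (-1, lo1, 1), (0, diag, 0),
                                  (1, up1, 0), (2, up2, 0)):
                v = np.asarray(vals)
                n_entries = v.size
                ii = i_idx[i_lo:i_lo + n_entries]
                g = ii * k + j
                g2 = (ii + b) * k + j
                ab[row0 + g - g2, g2] += -dt * v
    # unit diagonal
    ab[row0, :] += 1.0
    _, _, x, info = _dgbsv(kl, ku, ab, rhs, overwrite_ab=True,
                           overwrite_b=False)
    if info != 0:
        raise SimulationInstabilityError(
            f"coupled species banded solve failed (info={info})")
    return x

@_retrying
def simulate_multispecies(config: ModelConfig, init: FieldState,
                          production_fractions: Optional[np.ndarray] = None,
                          L_stop_factor: float = 2.0) -> Trajectory:
    """One generation (or a fraction, ``L_stop_factor``) with several
    polysome species.

    Each species i evolves with its own diffusion coefficient
    ``config.D_p_species[i]`` but a common chemical potential derived from
    the total polysome fraction (the free energy depends on total p).
    Nucleoid-templated production k1·n is split among the species according
    to ``production_fractions`` (equal split by default); degradation and
    growth dilution act on each species individually.
    """
    if config.D_p_species is None or len(config.D_p_species) < 2:
        raise ValueError("config.D_p_species must list at least two species")
    Ds = np.asarray(config.D_p_species, dtype=float)
    k = Ds.size
    fr = (np.full(k, 1.0 / k) if production_fractions is None
          else np.asarray(production_fractions, dtype=float))
    if fr.size != k or abs(float(fr.sum()) - 1.0) > 1e-9:
        raise ValueError("production fractions must sum to 1 (one per species)")

    state = init.copy()
    if state.p_species is None:
        state.p_species = np.outer(fr, state.p)
    stepper = Stepper(config)
    cfg = config
    gamma = cfg.growth.gamma_per_s
    h, dt = stepper.h, stepper.dt
    L_target = L_stop_factor * init.L
    rec = _Recorder(with_species=True)
    rec.record(state)
    stride = cfg.grid.sample_stride
    if gamma > 0:
        max_steps = int(np.ceil(np.log(max(L_stop_factor, 1.001)) / gamma / dt)) + 2
    else:
        max_steps = stride * 100
    i = 0
    fh = cfg.fh
    while state.L < L_target and i < max_steps:
        mu_p, mu_n = chemical_potentials(state, fh)
        lam2 = (fh.lambda_if / state.L) ** 2
        s = np.clip(1.0 - state.p - state.n, EPS_CLIP, None)
        fnn = 1.0 / (fh.v_n * state.n) + 1.0 / s - 2.0 * fh.chi_n
        k1 = cfg.k1
        loss = cfg.kinetics.k_deg + gamma
        m_j_all = fh.v_p * Ds[:, None] * state.p_species / state.L**2
        # each species carries its own translational entropy (ln p_j), while
        # the interaction and interfacial parts depend on the total p:
        # μ_j = μ_p(total) + (ln p_j − ln p)/v_p.  The interfacial part
        # couples every species to the total, so the implicit update is a
        # coupled k·N banded system; the entropy term is species-diagonal.
        fpp_shared = 1.0 / s - 2.0 * fh.chi_p
        shared_bands = [
            stepper._jacobian_bands(0.5 * (m_j_all[j, 1:] + m_j_all[j, :-1]),
                                    fpp_shared, 2.0 * fh.chi_p * lam2)
            for j in range(k)]
        pj_safe = np.clip(state.p_species, EPS_CLIP, None)
        own_bands = [
            stepper._jacobian_bands(0.5 * (m_j_all[j, 1:] + m_j_all[j, :-1]),
                                    1.0 / (fh.v_p * pj_safe[j]), 0.0)
            for j in range(k)]
        rhs = np.empty(k * stepper.N)
        log_ratio = np.log(pj_safe / np.clip(state.p, EPS_CLIP, None))
        for j in range(k):
            mu_j = mu_p + log_ratio[j] / fh.v_p
            rhs_j = (div_flux(m_j_all[j], mu_j, h)
                     + fr[j] * k1 * state.n - loss * state.p_species[j])
            rhs[j::k] = (state.p_species[j] + dt * rhs_j
                         - dt * stepper._apply_bands(shared_bands[j], state.p)
                         - dt * stepper._apply_bands(own_bands[j],
                                                     state.p_species[j]))
        sol = _coupled_species_solve(shared_bands, rhs, dt, k, stepper.N,
                                     own_bands=own_bands)
        # species shares may graze zero where one species is locally depleted;
        # only a substantial excursion indicates a genuine instability
        if not np.all(np.isfinite(sol)) or np.any(sol < -0.02):
            raise SimulationInstabilityError("species fields unstable")
        new_species = np.clip(np.stack([sol[j::k] for j in range(k)]),
                              0.0, 1.0 - EPS_CLIP)
        p_tot_new = np.clip(new_species.sum(axis=0), EPS_CLIP, 1.0 - EPS_CLIP)
        m_n = fh.v_n * cfg.kinetics.D_n * state.n / state.L**2
        bands_n = stepper._jacobian_bands(0.5 * (m_n[1:] + m_n[:-1]), fnn,
                                          2.0 * fh.chi_n * lam2)
        rhs_n = (state.n + dt * div_flux(m_n, mu_n, h)
                 - dt * stepper._apply_bands(bands_n, state.n))
        n_new = stepper._clip_or_raise(stepper._implicit_solve(rhs_n, bands_n),
                                       "nucleoid")
        tot = p_tot_new + n_new
        over = tot >= 1.0 - EPS_CLIP
        if np.any(over):  # keep the solvent fraction positive
            scale = (1.0 - 2.0 * EPS_CLIP) / tot[over]
            p_tot_new[over] *= scale
            n_new[over] *= scale
            new_species[:, over] *= scale
        state = FieldState(p=p_tot_new, n=n_new,
                           L=state.L * float(np.exp(gamma * dt)),
                           t=state.t + dt, p_species=new_species)
        i += 1
        if i % stride == 0:
            rec.record(state)
    if i % stride != 0:
        rec.record(state)
    return rec.build()
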