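"""In-silico experiments on the segregation model.

Reduces simulated trajectories to the summary quantities used to
characterise the model: splitting-time detection by mid-cell nucleoid
depletion, the growth-rate sweep with generational chaining, the
nucleoid-diffusivity (quasi-steady-state) sweep, and the ectopic polysome
production scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fields import FieldState, grid_centers
from .params import (EctopicSource, GrowthSpec, ModelConfig,
                     SWEEP_GROWTH_RATES_PER_H, birth_length)
from .simulate import (Trajectory, divide, initial_steady_state,
                       relax_to_steady_state, simulate_generation,
                       spread_nucleoid_state)

__all__ = [
    "SplitEvent",
    "SweepRow",
    "detect_splitting",
    "growth_rate_sweep",
    "equilibrium_deviation",
    "ectopic_scenarios",
    "compaction_benchmark",
    "newborn_summaries",
    "nucleoid_centroid",
    "nucleoid_peak_positions",
]

#: default depletion threshold marking nucleoid splitting
SPLIT_DEPLETION_THRESHOLD = 0.30


@dataclass(frozen=True)
class SplitEvent:
    """Nucleoid-splitting event detected on a trajectory."""

    detected: bool
    t_split: float = np.nan          # s since birth
    relative_timing: float = np.nan  # fraction of the birth-to-division interval
    L_at_split: float = np.nan       # μm

    def __post_init__(self) -> None:
        if self.detected and not (0.0 <= self.relative_timing <= 1.0):
            raise ValueError("relative timing must lie in [0, 1] when detected")


@dataclass(frozen=True)
class SweepRow:
    """One growth rate of the sweep, with its newborn asymmetry summaries."""

    gamma: float                 # h^-1
    L0: float                    # μm
    detected: bool
    t_split: float               # s
    relative_timing: float
    L_at_split: float            # μm
    newborn_polar_ratio: float   # polysome concentration, new pole / old pole
    newborn_nuc_offset_um: float  # nucleoid centroid, + toward new pole


def _center_series(traj: Trajectory) -> np.ndarray:
    N = traj.n.shape[1]
    return traj.n[:, N // 2 - 1: N // 2 + 1].mean(axis=1)


def detect_splitting(traj: Trajectory,
                     threshold: float = SPLIT_DEPLETION_THRESHOLD) -> SplitEvent:
    """Detect nucleoid splitting by relative mid-cell depletion.

    Splitting is marked at the first sample where the nucleoid concentration
    at the cell centre has dropped by at least ``threshold`` relative to its
    running maximum since birth.  The relative timing is the split time as a
    fraction of the trajectory's birth-to-division interval.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    c = _center_series(traj)
    running = np.maximum.accumulate(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        depletion = 1.0 - c / running
    if threshold == 0.0:
        hits = np.nonzero(depletion > 0.0)[0]
    else:
        hits = np.nonzero(depletion >= threshold)[0]
    if hits.size == 0:
        return SplitEvent(detected=False)
    i = int(hits[0])
    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    t_split = float(traj.times[i]) - t0
    span = t1 - t0
    rel = t_split / span if span > 0 else np.nan
    return SplitEvent(detected=True, t_split=t_split,
                      relative_timing=min(max(rel, 0.0), 1.0),
                      L_at_split=float(traj.lengths[i]))


# ---------------------------------------------------------------------------
# newborn summaries (shared code path with the profile quantification layer)

def state_to_profile(state: FieldState, channel: str):
    """View a simulated field as a quantification-layer Profile.

    Positions run from the old pole (−1) to the new pole (+1), matching the
    orientation convention of experimental profiles.
    """
    from .profiles import Profile  # local import to avoid a cycle
    values = state.p if channel == "polysome" else state.n
    x = grid_centers(state.N) * 2.0 - 1.0
    return Profile(positions=x, values=values.copy(), cell_length_um=state.L,
                   channel=channel)


def nucleoid_centroid(state: FieldState) -> float:
    """Nucleoid centre of mass in rescaled coordinates (0 … 1)."""
    x = grid_centers(state.N)
    return float(np.sum(x * state.n) / np.sum(state.n))


def nucleoid_peak_positions(state: FieldState, min_height: float = 0.05,
                            ) -> np.ndarray:
    """Rescaled positions of interior local maxima of the nucleoid field."""
    n = state.n
    interior = np.nonzero((n[1:-1] > n[:-2]) & (n[1:-1] >= n[2:])
                          & (n[1:-1] > min_height))[0] + 1
    return grid_centers(state.N)[interior]


def newborn_summaries(newborn: FieldState, polar_fraction: float = 0.1,
                      ) -> Dict[str, float]:
    """Polarity summaries of a newborn state (new pole at x̃ = 1).

    Returns the polysome polar concentration ratio (new/old pole, mean over
    the outer ``polar_fraction`` of the cell) and the nucleoid centroid
    offset in μm (positive toward the new pole).
    """
    N = newborn.N
    k = max(1, int(round(polar_fraction * N)))
    p = newborn.p
    ratio = float(np.mean(p[-k:]) / np.mean(p[:k]))
    offset = (nucleoid_centroid(newborn) - 0.5) * newborn.L
    return {"polar_ratio": ratio, "nuc_offset_um": float(offset)}


# ---------------------------------------------------------------------------
# benchmark: fixed-length compaction of a spread nucleoid

def compaction_benchmark(config: Optional[ModelConfig] = None,
                         tol: float = 1e-8, n_mean: float = 0.30,
                         sigma: float = 0.30,
                         ) -> Tuple[FieldState, float]:
    """Relax a non-growing cell with a spread nucleoid to steady state.

    A 2.2 μm cell is initialised with homogeneous polysomes and a nucleoid
    spread throughout most of the cell; the mixture demixes and the nucleoid
    compacts at mid-cell.  Returns the steady state and the model time taken
    to reach it (max field rate < ``tol`` per second).
    """
    if config is None:
        config = ModelConfig(growth=GrowthSpec(gamma=0.0, L0=2.2))
    init = spread_nucleoid_state(config, n_mean=n_mean, sigma=sigma)
    return relax_to_steady_state(config, init, tol=tol)


# ---------------------------------------------------------------------------
# growth-rate sweep with generational chaining

def growth_rate_sweep(gammas: Sequence[float] = SWEEP_GROWTH_RATES_PER_H,
                      config: Optional[ModelConfig] = None,
                      threshold: float = SPLIT_DEPLETION_THRESHOLD,
                      ) -> List[SweepRow]:
    """One generation per growth rate, chained through division.

    Birth length per growth rate follows the empirical regression
    L0 = 2.00·exp(γ/2.81 h⁻¹).  The first generation starts from the
    symmetric steady state at its birth length; every following growth rate
    starts from one daughter of the previous generation's predivisional
    state, linearly rescaled to the new birth length (this carries the
    new/old-pole asymmetries from generation to generation).
    """
    if len(gammas) == 0:
        raise ValueError("need at least one growth rate")
    if config is None:
        config = ModelConfig()
    rows: List[SweepRow] = []
    init: Optional[FieldState] = None
    for gamma in gammas:
        L0 = birth_length(gamma)
        cfg = config.with_growth(gamma, L0)
        if init is None:
            init = initial_steady_state(cfg)
        else:
            init.L = L0  # rescale the inherited daughter to this birth length
            init.t = 0.0
        try:
            traj = simulate_generation(cfg, init)
        except Exception:
            rows.append(SweepRow(gamma=gamma, L0=L0, detected=False,
                                 t_split=np.nan, relative_timing=np.nan,
                                 L_at_split=np.nan, newborn_polar_ratio=np.nan,
                                 newborn_nuc_offset_um=np.nan))
            init = None
            continue
        event = detect_splitting(traj, threshold)
        daughter, _ = divide(traj.final_state, cfg)
        summ = newborn_summaries(daughter)
        rows.append(SweepRow(gamma=gamma, L0=L0, detected=event.detected,
                             t_split=event.t_split,
                             relative_timing=event.relative_timing,
                             L_at_split=event.L_at_split,
                             newborn_polar_ratio=summ["polar_ratio"],
                             newborn_nuc_offset_um=summ["nuc_offset_um"]))
        init = daughter
    return rows


def sweep_table(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# nucleoid-diffusivity sweep: deviation of newborns from the steady state

def equilibrium_deviation(Dn_values: Sequence[float] = (0.0005, 0.001, 0.005),
                          gamma: float = 0.57,
                          config: Optional[ModelConfig] = None,
                          ) -> pd.DataFrame:
    """Deviation of newborn profiles from the infinitely-relaxed steady state.

    For each nucleoid diffusion coefficient, one generation is simulated at
    the given growth rate from the symmetric steady state; the newborn
    (post-division) profiles are compared to the fixed-length steady-state
    profiles at the same birth length.  The deviation is the L² distance on
    the rescaled domain, computed per field and summed.  The steady state
    itself is independent of D_n (D_n only sets the relaxation speed), so
    the reference is relaxed once with the largest D_n of the sweep.
    """
    if config is None:
        config = ModelConfig()
    L0 = birth_length(gamma)
    ref_cfg = replace(config.with_growth(gamma, L0),
                      kinetics=replace(config.kinetics,
                                       D_n=max(max(Dn_values), 0.005)))
    reference = initial_steady_state(ref_cfg)
    h = 1.0 / config.grid.N
    out = []
    for Dn in Dn_values:
        cfg = replace(config.with_growth(gamma, L0),
                      kinetics=replace(config.kinetics, D_n=Dn))
        init = initial_steady_state(cfg)
        traj = simulate_generation(cfg, init)
        newborn, _ = divide(traj.final_state, cfg)
        dev_p = float(np.sqrt(np.sum((newborn.p - reference.p) ** 2) * h))
        dev_n = float(np.sqrt(np.sum((newborn.n - reference.n) ** 2) * h))
        summ = newborn_summaries(newborn)
        out.append({"D_n": Dn, "deviation": dev_p + dev_n,
                    "deviation_p": dev_p, "deviation_n": dev_n,
                    "polar_ratio": summ["polar_ratio"],
                    "nuc_offset_um": summ["nuc_offset_um"]})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ectopic production scenarios

POLAR_SOURCE = EctopicSource(kind="polar", amplitude=0.8, extent=0.8,
                             k1_reduction=0.5)
MIDCELL_SOURCE = EctopicSource(kind="midcell", amplitude=0.5, extent=0.4,
                               k1_reduction=0.5)


@dataclass
class EctopicResult:
    trajectories: Dict[str, Trajectory]
    summary: pd.DataFrame
    classifications: Dict[str, str]


def ectopic_scenarios(config: Optional[ModelConfig] = None,
                      gamma: float = 0.57) -> EctopicResult:
    """Run the polar and mid-cell ectopic production scenarios vs control.

    The polar source produces polysomes at 0.8·k1 within 0.8 μm of one pole
    (with nucleoid-templated production halved); the mid-cell source at
    0.5·k1 within 0.4 μm of mid-cell (also with k1' = 0.5·k1).  All three
    runs grow for one generation from the same symmetric steady state.
    The polar scenario is classified by the displacement of the nucleoid
    centre of mass away from the source pole relative to control; the
    mid-cell scenario by the inter-peak distance of the sister nucleoids at
    division relative to control.
    """
    if config is None:
        config = ModelConfig()
    L0 = birth_length(gamma)
    base = config.with_growth(gamma, L0)
    init = initial_steady_state(base)
    scenarios = {
        "control": replace(base, source=EctopicSource()),
        "polar": replace(base, source=POLAR_SOURCE),
        "midcell": replace(base, source=MIDCELL_SOURCE),
    }
    trajectories = {name: simulate_generation(cfg, init.copy())
                    for name, cfg in scenarios.items()}
    rows = []
    for name, traj in trajectories.items():
        final = traj.final_state
        peaks = nucleoid_peak_positions(final)
        sep = float((peaks.max() - peaks.min()) * final.L) if peaks.size >= 2 else 0.0
        rows.append({
            "scenario": name,
            "centroid": nucleoid_centroid(final),
            "peak_separation_um": sep,
            "split_detected": detect_splitting(traj).detected,
            "relative_timing": detect_splitting(traj).relative_timing,
        })
    summary = pd.DataFrame(rows).set_index("scenario")
    classifications = {}
    # source sits at the x̃=0 pole: displacement away from it = centroid above control
    if summary.loc["polar", "centroid"] > summary.loc["control", "centroid"]:
        classifications["polar"] = "nucleoid displaced away from source pole"
    else:
        classifications["polar"] = "no displacement away from source pole"
    if (summary.loc["midcell", "peak_separation_um"]
            > summary.loc["control", "peak_separation_um"]):
        classifications["midcell"] = "sister nucleoids pushed farther apart"
    else:
        classifications["midcell"] = "no extra sister separation"
    return EctopicResult(trajectories=trajectories, summary=summary,
                         classifications=classifications)
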