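"""Rate estimators on tracked nucleoid cycles and principal-component regression.

All rates are ordinary-least-squares slopes over defined windows of a
tracked series:

* polysome / nucleoid concentration at mid-nucleoid (a 5 px ≈ 0.33 μm
  window around the tracked nucleoid centre) against time, over 40–90% of
  the nucleoid segregation cycle — the interval from the initiation of
  nucleoid splitting to just before its completion;
* polysome concentration at mid-cell (central 10% of the cell length)
  against time, within the four quartiles of the split-to-division interval;
* ln inter-nucleoid distance and ln cell length against time, within the
  same quartiles (exponential migration / elongation rates).

Filters: windows with fewer than five timepoints, division cycles with a
negative elongation rate, and cells born with two nucleoid objects are
excluded, each with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

__all__ = ["RateEstimate", "rate_estimators", "pc_regression",
           "MIN_POINTS", "CYCLE_WINDOW"]

MIN_POINTS = 5           # "more than four timepoints"
CYCLE_WINDOW = (0.40, 0.90)
QUARTILES = ((0.0, 0.25), (0.25, 0.50), (0.50, 0.75), (0.75, 1.0 + 1e-12))


@dataclass(frozen=True)
class RateEstimate:
    """An OLS slope over a defined window of a tracked series."""

    quantity: str
    window: str
    slope: float            # per minute
    intercept: float
    n_points: int
    ok: bool
    reason: str = ""


def _ols(t_min: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    coef = np.polyfit(t_min, y, 1)
    return float(coef[0]), float(coef[1])


def _estimate(df: pd.DataFrame, col: str, sel: np.ndarray, quantity: str,
              window: str, log: bool = False) -> RateEstimate:
    sub = df.loc[sel, ["time_min", col]].dropna()
    n = len(sub)
    if n < MIN_POINTS:
        return RateEstimate(quantity, window, np.nan, np.nan, n, False,
                            f"only {n} timepoints (need > 4)")
    y = sub[col].to_numpy(dtype=float)
    if log:
        if np.any(y <= 0):
            return RateEstimate(quantity, window, np.nan, np.nan, n, False,
                                "non-positive values under log transform")
        y = np.log(y)
    slope, intercept = _ols(sub["time_min"].to_numpy(dtype=float), y)
    return RateEstimate(quantity, window, slope, intercept, n, True)


def rate_estimators(cycle: pd.DataFrame,
                    born_with_two_nucleoids: bool = False,
                    ) -> List[RateEstimate]:
    """Rate estimates for one tracked cell / nucleoid cycle.

    ``cycle`` is a tidy per-frame table with columns ``time_min`` plus any
    of: ``mid_nucleoid_polysome``, ``mid_nucleoid_nucleoid`` (with
    ``cycle_fraction`` ∈ [0, 1] over the nucleoid segregation cycle) and
    ``mid_cell_polysome``, ``internucleoid_distance_um``,
    ``cell_length_um`` (with ``split_to_div_fraction`` ∈ [0, 1]).
    """
    out: List[RateEstimate] = []
    if born_with_two_nucleoids:
        return [RateEstimate("all", "all", np.nan, np.nan, 0, False,
                             "cell born with two nucleoid objects")]
    if "cycle_fraction" in cycle:
        lo, hi = CYCLE_WINDOW
        sel = (cycle["cycle_fraction"] >= lo) & (cycle["cycle_fraction"] <= hi)
        for col, name in (("mid_nucleoid_polysome", "mid_nucleoid_polysome"),
                          ("mid_nucleoid_nucleoid", "mid_nucleoid_nucleoid")):
            if col in cycle:
                out.append(_estimate(cycle, col, sel, name, "cycle_40_90"))
    if "split_to_div_fraction" in cycle:
        frac = cycle["split_to_div_fraction"]
        # a negative whole-interval elongation rate voids the cell cycle
        elong_bad = False
        if "cell_length_um" in cycle:
            whole = _estimate(cycle, "cell_length_um",
                              np.ones(len(cycle), dtype=bool),
                              "ln_cell_length", "whole_interval", log=True)
            elong_bad = whole.ok and whole.slope < 0
        for qi, (lo, hi) in enumerate(QUARTILES, start=1):
            sel = ((frac >= lo) & (frac < hi)).to_numpy()
            window = f"quartile_{qi}"
            specs = (("mid_cell_polysome", "mid_cell_polysome", False),
                     ("internucleoid_distance_um", "ln_internucleoid_distance",
                      True),
                     ("cell_length_um", "ln_cell_length", True))
            for col, name, log in specs:
                if col not in cycle:
                    continue
                if elong_bad:
                    out.append(RateEstimate(name, window, np.nan, np.nan,
                                            int(sel.sum()), False,
                                            "negative cell elongation rate"))
                else:
                    out.append(_estimate(cycle, col, sel, name, window, log=log))
    return out


def pc_regression(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Principal-component (total-least-squares) regression.

    The first principal axis of the z-transformed pairs is rescaled to the
    original plane, eliminating the dependent-variable bias of an ordinary
    univariate fit.  Returns (slope, intercept) in original units.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 3:
        raise ValueError("need at least three finite pairs")
    sx, sy = float(np.std(x)), float(np.std(y))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate input: zero variance")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    cov = np.cov(np.vstack([zx, zy]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]  # first principal axis
    if v[0] == 0:
        raise ValueError("principal axis is vertical; slope undefined")
    slope = float(v[1] / v[0] * sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept
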