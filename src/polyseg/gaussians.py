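"""Gaussian decomposition of axial profiles and the derived asymmetry statistics.

Polysome profiles early in the division cycle are decomposed into three
Gaussians over a constant baseline — nucleoid-excluded accumulations at the
old pole and the new pole plus the rising mid-nucleoid accumulation.
Constricting-nucleoid profiles are decomposed into two Gaussians (old- and
new-pole lobes).  All positions are relative cell-length coordinates from
the old pole (−1) through the centre (0) to the new pole (+1).

From the fitted triplets derive:

    Poly_asym  = log10(Area_new / Area_old)          polar polysome asymmetry
    Nuc_pos    = (l_new + l_old)/2 · l_cell/2        nucleoid offset, μm (+ = new pole)
    Nuc_comp   = A_new / A_old                       nucleoid compaction asymmetry
    Poly_space = (l_new − l_mid) / (l_mid − l_old)   polysome-free space ratio

with Area = A·σ·√(2π).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import curve_fit

from .profiles import Profile

__all__ = [
    "GaussianComponent",
    "GaussianDecomposition",
    "fit_polysome_gaussians",
    "fit_nucleoid_gaussians",
    "gaussian_area",
    "asymmetry_stats",
]

#: fits are kept only when the residual RMS is below this fraction of the
#: profile's value range
RESIDUAL_RMS_THRESHOLD = 0.15


@dataclass(frozen=True)
class GaussianComponent:
    A: float        # amplitude, a.u.
    l: float        # mean, relative coordinate in [−1, 1]
    sigma: float    # width, relative units

    @property
    def area(self) -> float:
        return gaussian_area(self.A, self.sigma)


@dataclass
class GaussianDecomposition:
    """Fitted Gaussian components over a baseline for one profile.

    ``components`` are ordered by mean: old pole first, new pole last (with
    the mid-cell component in between for the polysome channel).
    """

    components: List[GaussianComponent]
    baseline: float
    channel: str
    residual_rms: float = np.nan     # relative to the profile value range
    converged: bool = True

    def __post_init__(self) -> None:
        means = [c.l for c in self.components]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("components must be ordered old → new")
        if any(c.A < 0 for c in self.components):
            raise ValueError("amplitudes must be non-negative")

    @property
    def ok(self) -> bool:
        return self.converged and self.residual_rms <= RESIDUAL_RMS_THRESHOLD

    @property
    def old(self) -> GaussianComponent:
        return self.components[0]

    @property
    def new(self) -> GaussianComponent:
        return self.components[-1]

    @property
    def mid(self) -> GaussianComponent:
        if len(self.components) != 3:
            raise AttributeError("mid component requires a 3-Gaussian fit")
        return self.components[1]

    def predict(self, l: np.ndarray) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        out = np.full_like(l, self.baseline)
        for c in self.components:
            out += c.A * np.exp(-0.5 * ((c.l - l) / c.sigma) ** 2)
        return out

    def summary(self) -> str:
        lines = [f"{self.channel} decomposition "
                 f"({len(self.components)} components + baseline)",
                 f"  baseline  {self.baseline:10.4g}",
                 f"  residual  {self.residual_rms:10.4g} (rel. RMS)"]
        names = (["old", "mid", "new"] if len(self.components) == 3
                 else ["old", "new"])
        for name, c in zip(names, self.components):
            lines.append(f"  {name:4s} A={c.A:9.4g}  l={c.l:+8.4f}  "
                         f"sigma={c.sigma:8.4f}  area={c.area:9.4g}")
        return "\n".join(lines)


def _multi_gauss(l, *params):
    k = (len(params) - 1) // 3
    out = np.full_like(l, params[-1])
    for i in range(k):
        A, mu, sig = params[3 * i: 3 * i + 3]
        out = out + A * np.exp(-0.5 * ((mu - l) / sig) ** 2)
    return out


def _fit(profile: Profile, init_means, channel: str) -> GaussianDecomposition:
    l = profile.positions
    y = profile.values.astype(float)
    rng = float(np.max(y) - np.min(y))
    if rng <= 0:
        return GaussianDecomposition(
            components=[GaussianComponent(0.0, m, 0.2) for m in init_means],
            baseline=float(np.mean(y)), channel=channel, residual_rms=0.0)
    base0 = float(np.min(y))
    amp0 = rng
    p0, lower, upper = [], [], []
    for m in init_means:
        p0 += [amp0, m, 0.2]
        lower += [0.0, -1.0, 0.02]
        upper += [np.inf, 1.0, 2.0]
    p0.append(base0)
    lower.append(0.0)
    upper.append(np.inf)
    try:
        popt, _ = curve_fit(_multi_gauss, l, y, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        converged = False
    comps = [GaussianComponent(float(popt[3 * i]), float(popt[3 * i + 1]),
                               float(popt[3 * i + 2]))
             for i in range(len(init_means))]
    comps.sort(key=lambda c: c.l)
    resid = y - _multi_gauss(l, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)) / rng)
    return GaussianDecomposition(components=comps, baseline=float(popt[-1]),
                                 channel=channel, residual_rms=rms,
                                 converged=converged)


def fit_polysome_gaussians(profile: Profile) -> GaussianDecomposition:
    """Three Gaussians + baseline: old pole, mid-nucleoid, new pole.

    Initialised at l ≈ −0.9, 0, +0.9 with means bounded to [−1, 1] and
    non-negative amplitudes.  The fit is flagged (``ok`` False) when the
    optimiser fails or the relative residual RMS exceeds the acceptance
    threshold.
    """
    return _fit(profile, (-0.9, 0.0, 0.9), "polysome")


def fit_nucleoid_gaussians(profile: Profile) -> GaussianDecomposition:
    """Two Gaussians + baseline for a constricting nucleoid (lobes at ∓0.5)."""
    return _fit(profile, (-0.5, 0.5), "nucleoid")


def gaussian_area(A: float, sigma: float) -> float:
    """Area under a Gaussian of amplitude A and width σ: A·σ·√(2π)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(A * sigma * np.sqrt(2.0 * np.pi))


def asymmetry_stats(poly: Optional[GaussianDecomposition],
                    nuc: Optional[GaussianDecomposition],
                    cell_length_um: float) -> Dict[str, float]:
    """Polar asymmetry statistics from the fitted decompositions.

    Any statistic whose denominator is non-positive is returned as NaN
    (undefined).  ``poly`` or ``nuc`` may be None when only one channel was
    fitted.
    """
    out: Dict[str, float] = {"poly_asym": np.nan, "nuc_pos_um": np.nan,
                             "nuc_comp": np.nan, "poly_space": np.nan}
    if poly is not None:
        if len(poly.components) != 3:
            raise ValueError("polysome decomposition must have 3 components")
        area_old, area_new = poly.old.area, poly.new.area
        if area_old > 0 and area_new > 0:
            out["poly_asym"] = float(np.log10(area_new / area_old))
        gap_old = poly.mid.l - poly.old.l
        gap_new = poly.new.l - poly.mid.l
        if gap_old > 0:
            out["poly_space"] = float(gap_new / gap_old)
    if nuc is not None:
        if len(nuc.components) != 2:
            raise ValueError("nucleoid decomposition must have 2 components")
        out["nuc_pos_um"] = float(0.5 * (nuc.new.l + nuc.old.l)
                                  * cell_length_um / 2.0)
        if nuc.old.A > 0:
            out["nuc_comp"] = float(nuc.new.A / nuc.old.A)
    return out
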