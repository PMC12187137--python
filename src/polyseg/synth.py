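"""Ground-truthed synthetic data emulating the microscopy-derived inputs.

Every generator returns machine-readable ground truth next to its outputs,
so the quantification layer can be verified without real images: growing,
dividing cells with two fluorescence channels (a polysome-like channel with
polar + rising mid-cell Gaussian enrichments and a nucleoid-like channel
with one or two lobes), multiplicative cell-to-cell intensity variability,
additive Gaussian noise, exponential elongation, division with pole
identity, bent-rod masks with known centerlines and diffraction-limited
particle spots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import CellMask, DEFAULT_PIXEL_SIZE_UM
from .particles import gaussian2d_rotated
from .profiles import Profile, n_bins_for_length

__all__ = [
    "SynthConfig",
    "ProfileBundle",
    "generate_profile_series",
    "generate_lineage",
    "generate_bent_rod_mask",
    "generate_particle_image",
    "generate_fusion_series",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic population.

    Growth rates are per hour with the stated coefficient of variation; the
    birth length follows L0 = l0·exp(γ/γ0).  The polysome channel is a
    baseline plus three Gaussians (old pole, mid-cell — rising linearly
    through the cycle — and new pole); the nucleoid channel is one lobe that
    splits into two at ``split_fraction`` of the cycle, with a compaction
    asymmetry between the new- and old-pole lobes.  Noise is additive
    Gaussian per bin plus a lognormal per-cell intensity factor.
    """

    seed: int = 0
    n_founders: int = 3
    generations: int = 2
    frames_per_cycle: int = 21
    gamma_mean: float = 0.57        # h^-1
    gamma_cv: float = 0.10
    l0_um: float = 2.00
    gamma0_per_h: float = 2.81
    split_fraction: float = 0.60    # scripted splitting time, fraction of cycle
    baseline: float = 100.0         # a.u.
    polar_amp_old: float = 120.0
    polar_area_ratio: float = 1.3   # new/old polysome area ratio (equal widths)
    mid_amp_max: float = 90.0
    nuc_amp: float = 250.0
    compaction_asym: float = 1.25   # nucleoid new/old amplitude ratio
    gauss_sigma_rel: float = 0.12   # component width, relative coordinates
    nuc_sigma_rel: float = 0.16
    polar_mean: float = 0.85        # |position| of the polar components
    noise_sigma: float = 0.0        # additive, a.u.
    intensity_cv: float = 0.0       # lognormal per-cell factor
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM


@dataclass
class ProfileBundle:
    """Synthetic profiles plus lineage and the generating script."""

    profiles: List[Profile]
    lineage: pd.DataFrame
    truth: Dict

    def channel(self, name: str) -> List[Profile]:
        return [p for p in self.profiles if p.channel == name]

    def cell(self, cell_id: int, channel: Optional[str] = None) -> List[Profile]:
        out = [p for p in self.profiles if p.meta["cell_id"] == cell_id]
        if channel is not None:
            out = [p for p in out if p.channel == channel]
        return sorted(out, key=lambda p: p.meta["frame"])


def _polysome_components(cfg: SynthConfig, f: float) -> List[Tuple[float, float, float]]:
    """(A, mean, sigma) triples of the polysome channel at cycle fraction f."""
    a_old = cfg.polar_amp_old
    a_new = cfg.polar_amp_old * cfg.polar_area_ratio  # equal widths
    a_mid = cfg.mid_amp_max * f                        # rises linearly
    s = cfg.gauss_sigma_rel
    return [(a_old, -cfg.polar_mean, s), (a_mid, 0.0, s),
            (a_new, cfg.polar_mean, s)]


def _nucleoid_components(cfg: SynthConfig, f: float) -> List[Tuple[float, float, float]]:
    s = cfg.nuc_sigma_rel
    if f < cfg.split_fraction:
        return [(cfg.nuc_amp, 0.0, s)]
    # lobes separate linearly after the scripted split
    prog = (f - cfg.split_fraction) / max(1e-9, 1.0 - cfg.split_fraction)
    sep = 0.15 + 0.35 * prog
    r = cfg.compaction_asym
    a_old = 2.0 * cfg.nuc_amp / (1.0 + r)
    return [(a_old, -sep, s), (a_old * r, sep, s)]


def _render(components, positions: np.ndarray, baseline: float) -> np.ndarray:
    out = np.full_like(positions, baseline)
    for A, mu, sig in components:
        out = out + A * np.exp(-0.5 * ((mu - positions) / sig) ** 2)
    return out


def generate_profile_series(config: SynthConfig) -> ProfileBundle:
    """Per-frame two-channel axial profiles over ≥ 2 generations.

    Founder cells are placed in non-overlapping channel intervals; each cell
    grows exponentially for one cycle (frames at equally spaced cycle
    fractions), divides at mid-cell, and both daughters are followed.
    Profiles are polarity-oriented (old pole at −1).  All scripted component
    trajectories, splitting frames and asymmetry targets are returned in
    ``truth``; with zero noise the profiles equal the scripted sums exactly.
    """
    rng = np.random.default_rng(config.seed)
    profiles: List[Profile] = []
    lineage_rows = []
    truth: Dict = {"cells": {}, "config": config}
    next_id = [0]

    def new_cell(mother_id, pos_lo, pos_hi, new_pole_side, birth_frame,
                 generation) -> int:
        cid = next_id[0]
        next_id[0] += 1
        lineage_rows.append({
            "cell_id": cid, "mother_id": mother_id,
            "pos_lo": pos_lo, "pos_hi": pos_hi,
            "birth_frame": birth_frame, "generation": generation,
            "new_pole_side": new_pole_side,
        })
        return cid

    def simulate_cell(cid: int, generation: int, birth_frame: int) -> None:
        row = lineage_rows[cid]
        gamma = max(0.05, rng.normal(config.gamma_mean,
                                     config.gamma_cv * config.gamma_mean))
        L0 = config.l0_um * np.exp(gamma / config.gamma0_per_h)
        T_min = np.log(2.0) / gamma * 60.0
        factor = (rng.lognormal(mean=0.0, sigma=config.intensity_cv)
                  if config.intensity_cv > 0 else 1.0)
        fracs = np.linspace(0.0, 1.0, config.frames_per_cycle)
        split_frame = None
        cell_truth = {"gamma_per_h": gamma, "L0_um": L0,
                      "intensity_factor": factor, "frames": {},
                      "split_fraction": config.split_fraction,
                      "poly_asym_target": float(np.log10(config.polar_area_ratio)),
                      "nuc_comp_target": config.compaction_asym}
        for j, f in enumerate(fracs):
            frame = birth_frame + j
            length = L0 * 2.0 ** f
            nb = max(10, n_bins_for_length(length))
            pos = np.linspace(-1.0 + 1.0 / nb, 1.0 - 1.0 / nb, nb)
            comps_p = _polysome_components(config, f)
            comps_n = _nucleoid_components(config, f)
            if split_frame is None and len(comps_n) == 2:
                split_frame = frame
            for channel, comps in (("polysome", comps_p), ("nucleoid", comps_n)):
                clean = _render(comps, pos, config.baseline) * factor
                noisy = clean + (rng.normal(0.0, config.noise_sigma, nb)
                                 if config.noise_sigma > 0 else 0.0)
                profiles.append(Profile(
                    positions=pos, values=noisy, cell_length_um=length,
                    channel=channel,
                    meta={"cell_id": cid, "frame": frame,
                          "cycle_fraction": float(f),
                          "time_min": float(f * T_min),
                          "generation": generation}))
            cell_truth["frames"][frame] = {
                "cycle_fraction": float(f), "length_um": float(length),
                "polysome_components": comps_p,
                "nucleoid_components": comps_n,
            }
        cell_truth["split_frame"] = split_frame
        truth["cells"][cid] = cell_truth
        div_frame = birth_frame + config.frames_per_cycle
        lineage_rows[cid]["division_frame"] = div_frame
        if generation + 1 >= config.generations:
            return
        lo, hi = row["pos_lo"], row["pos_hi"]
        mid = 0.5 * (lo + hi)
        # lower daughter's new pole faces the former mid-cell ("hi" side)
        d1 = new_cell(cid, lo, mid, "hi", div_frame, generation + 1)
        d2 = new_cell(cid, mid, hi, "lo", div_frame, generation + 1)
        simulate_cell(d1, generation + 1, div_frame)
        simulate_cell(d2, generation + 1, div_frame)

    for i in range(config.n_founders):
        cid = new_cell(None, 10.0 * i, 10.0 * i + 5.0, "hi", 0, 0)
        simulate_cell(cid, 0, 0)

    lineage = pd.DataFrame(lineage_rows)
    return ProfileBundle(profiles=profiles, lineage=lineage, truth=truth)


def generate_lineage(config: SynthConfig) -> pd.DataFrame:
    """Linked lineage tree with polarity and age-class ground truth.

    Builds the interval tree of :func:`generate_profile_series` without
    rendering profiles, and adds the generator's own truth labels for
    polarity and the six age classes plus the nucleoid inheritance group of
    each daughter (±1 new-pole inheritance, ±2 old-pole inheritance).
    """
    if config.generations < 2:
        raise ValueError("need at least two generations")
    rows = []
    next_id = [0]

    def build(mother, lo, hi, side, gen, mother_class, mother_side):
        cid = next_id[0]
        next_id[0] += 1
        if mother is None:
            age = 1
        else:
            same = side == mother_side
            from .geometry import AGE_RULES
            age = AGE_RULES.get((mother_class, same), 0) \
                if mother_class not in (0, -1) else 0
        group = None
        if mother is not None:
            inherits_new = side != mother_side
            group = (1 if inherits_new else 2) * (1 if side == "hi" else -1)
        rows.append({"cell_id": cid, "mother_id": mother,
                     "pos_lo": lo, "pos_hi": hi, "generation": gen,
                     "new_pole_side_truth": side, "age_class_truth": age,
                     "inheritance_group_truth": group})
        if gen + 1 < config.generations:
            mid = 0.5 * (lo + hi)
            build(cid, lo, mid, "hi", gen + 1, age, side)
            build(cid, mid, hi, "lo", gen + 1, age, side)

    for i in range(config.n_founders):
        build(None, 10.0 * i, 10.0 * i + 5.0, "hi", 0, None, None)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster generators

def generate_bent_rod_mask(length_um: float = 3.0, width_um: float = 0.9,
                           curvature_per_um: float = 0.0,
                           pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                           pad_px: int = 6,
                           ) -> Tuple[CellMask, np.ndarray]:
    """Rasterized capsule along a circular-arc centerline, with the truth.

    ``length_um`` is the arc length of the capsule spine; the cell spans
    ``length_um + width_um`` pole to pole (hemispherical caps).  Returns the
    mask and the true pole-to-pole medial axis — the spine extended
    tangentially by half a width into each cap — as an (M, 2) array of
    (x, y) sub-pixel coordinates.  ``curvature_per_um`` = 0 gives a straight
    rod whose centerline is the chord.
    """
    if not width_um < length_um:
        raise ValueError("width must be smaller than length")
    s = np.linspace(0.0, length_um, 600)
    if curvature_per_um == 0.0:
        xs, ys = s, np.zeros_like(s)
    else:
        R = 1.0 / curvature_per_um
        phi = s / R
        xs = R * np.sin(phi)
        ys = R * (1.0 - np.cos(phi))
    # tangential extensions to the cap tips (the capsule's true medial axis)
    n_ext = 120
    t_head = np.array([xs[0] - xs[1], ys[0] - ys[1]])
    t_head /= np.linalg.norm(t_head)
    t_tail = np.array([xs[-1] - xs[-2], ys[-1] - ys[-2]])
    t_tail /= np.linalg.norm(t_tail)
    ext = np.linspace(0.5 * width_um, 0.0, n_ext, endpoint=False)
    head = np.column_stack([xs[0] + ext * t_head[0], ys[0] + ext * t_head[1]])
    tail = np.column_stack([xs[-1] + ext[::-1] * t_tail[0],
                            ys[-1] + ext[::-1] * t_tail[1]])
    spine_xs, spine_ys = xs, ys
    xs = np.concatenate([head[:, 0], xs, tail[:, 0]])
    ys = np.concatenate([head[:, 1], ys, tail[:, 1]])
    xs_px = xs / pixel_size
    ys_px = ys / pixel_size
    half_w = 0.5 * width_um / pixel_size
    x0 = xs_px.min() - half_w - pad_px
    y0 = ys_px.min() - half_w - pad_px
    xs_px -= x0
    ys_px -= y0
    nx = int(np.ceil(xs_px.max() + half_w + pad_px))
    ny = int(np.ceil(ys_px.max() + half_w + pad_px))
    yy, xx = np.mgrid[0:ny, 0:nx]
    from scipy.spatial import cKDTree
    spine_px = np.column_stack([spine_xs / pixel_size - x0,
                                spine_ys / pixel_size - y0])
    tree = cKDTree(spine_px)
    d, _ = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
    mask = (d.reshape(ny, nx) <= half_w)
    centerline = np.column_stack([xs_px, ys_px])
    return CellMask(mask=mask, pixel_size=pixel_size), centerline


def generate_particle_image(center: Tuple[float, float] = (7.2, 6.8),
                            A: float = 200.0,
                            sigmas: Tuple[float, float] = (1.3, 1.7),
                            theta: float = 0.0, noise_sigma: float = 0.0,
                            seed: int = 0, shape: Tuple[int, int] = (15, 15),
                            second_center: Optional[Tuple[float, float]] = None,
                            ) -> Tuple[np.ndarray, Dict]:
    """Rotated-Gaussian spot image (optionally two spots) plus ground truth.

    ``center`` is the true particle centre in image coordinates; the
    rotated-frame parameters are derived so the forward model matches the
    localization fit's convention exactly.
    """
    ny, nx = shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    rng = np.random.default_rng(seed)

    def spot(cx, cy):
        c, sn = np.cos(theta), np.sin(theta)
        x0 = cx * c - cy * sn
        y0 = cx * sn + cy * c
        return gaussian2d_rotated(xs.astype(float), ys.astype(float),
                                  A, x0, y0, sigmas[0], sigmas[1], theta)

    img = spot(*center)
    truth = {"centers": [tuple(map(float, center))], "A": A,
             "sigmas": sigmas, "theta": theta}
    if second_center is not None:
        img = img + spot(*second_center)
        truth["centers"].append(tuple(map(float, second_center)))
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return img, truth


def generate_fusion_series(fusing: bool, n_frames: int = 12,
                           cell_length_um: float = 6.0,
                           amplitude: float = 300.0, baseline: float = 20.0,
                           fusion_frame: int = 6, noise_sigma: float = 0.0,
                           seed: int = 0) -> Tuple[List[Profile], Dict]:
    """Scripted two-nucleoid time series for fusion classification tests.

    In the fusing variant the two lobes approach and merge into one at
    ``fusion_frame``; otherwise they keep a constant separation.  Division
    is blocked (constant cell length), mimicking drug-treated filaments.
    """
    rng = np.random.default_rng(seed)
    nb = n_bins_for_length(cell_length_um)
    pos = np.linspace(-1.0 + 1.0 / nb, 1.0 - 1.0 / nb, nb)
    profiles = []
    sep0 = 0.5
    for f in range(n_frames):
        if fusing:
            prog = min(1.0, f / max(1, fusion_frame))
            sep = sep0 * (1.0 - prog)
        else:
            sep = sep0
        if fusing and f >= fusion_frame:
            comps = [(amplitude, 0.0, 0.12)]
        else:
            comps = [(amplitude, -sep, 0.10), (amplitude, sep, 0.10)]
        vals = _render(comps, pos, baseline)
        if noise_sigma > 0:
            vals = vals + rng.normal(0.0, noise_sigma, nb)
        profiles.append(Profile(positions=pos, values=vals,
                                cell_length_um=cell_length_um,
                                channel="nucleoid",
                                meta={"frame": f, "cell_id": 0}))
    script = {"fusing": fusing,
              "fusion_frame": fusion_frame if fusing else None,
              "initial_separation_um": sep0 * cell_length_um}
    return profiles, script
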