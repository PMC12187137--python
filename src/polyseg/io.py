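"""Configuration files, tidy-table serialization and raster I/O.

Configuration is structured YAML with units spelled out in the key names
(``gamma_per_hour``, ``D_n_um2_s`` …) because the source literature mixes
h⁻¹ and s⁻¹ freely — conversions happen exactly once, at this boundary.
Profiles and statistics travel as tidy CSV tables (one row per
observation); label masks as integer TIFF planes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .params import (EctopicSource, FloryHugginsParams, GridSpec, GrowthSpec,
                     KineticParams, ModelConfig)
from .profiles import Profile
from .simulate import Trajectory
from .synth import SynthConfig

__all__ = [
    "load_yaml", "dump_yaml",
    "model_config_from_dict", "model_config_to_dict",
    "synth_config_from_dict",
    "profiles_to_frame", "frame_to_profiles",
    "save_trajectory", "load_trajectory",
    "write_label_mask", "read_label_mask",
]

PathLike = Union[str, Path]


def load_yaml(path: PathLike) -> Dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def dump_yaml(data: Dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _section(d: Dict, name: str) -> Dict:
    sec = d.get(name, {})
    if sec is None:
        sec = {}
    if not isinstance(sec, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return sec


def model_config_from_dict(d: Dict) -> ModelConfig:
    """Build a ModelConfig from a units-explicit mapping.

    Validation errors are re-raised with the config section for context.
    """
    try:
        fh_sec = _section(d, "interactions")
        fh = FloryHugginsParams(
            chi_p=fh_sec.get("chi_p", 0.2),
            chi_n=fh_sec.get("chi_n", 0.4),
            chi_np=fh_sec.get("chi_np", 1.2),
            lambda_if=fh_sec.get("lambda_if_um", 0.03),
            v_p=fh_sec.get("v_p", 5.0),
            v_n=fh_sec.get("v_n", 10.0))
    except ValueError as err:
        raise ValueError(f"interactions: {err}") from err
    try:
        kin_sec = _section(d, "kinetics")
        kin = KineticParams(
            D_p=kin_sec.get("D_p_um2_s", 0.023),
            D_n=kin_sec.get("D_n_um2_s", 0.001),
            k1_0=kin_sec.get("k1_0_per_s", 0.002),
            k_deg=kin_sec.get("k_deg_per_s", 0.003))
    except ValueError as err:
        raise ValueError(f"kinetics: {err}") from err
    try:
        g_sec = _section(d, "growth")
        growth = GrowthSpec(gamma=g_sec.get("gamma_per_hour", 0.0),
                            L0=g_sec.get("L0_um"))
    except ValueError as err:
        raise ValueError(f"growth: {err}") from err
    try:
        grid_sec = _section(d, "grid")
        grid = GridSpec(N=grid_sec.get("N", 128),
                        dt=grid_sec.get("dt_s", 0.05),
                        sample_stride=grid_sec.get("sample_stride", 200))
    except ValueError as err:
        raise ValueError(f"grid: {err}") from err
    try:
        s_sec = _section(d, "source")
        source = EctopicSource(kind=s_sec.get("kind", "none"),
                               amplitude=s_sec.get("amplitude_k1", 0.0),
                               extent=s_sec.get("extent_um", 0.0),
                               k1_reduction=s_sec.get("k1_reduction", 1.0))
    except ValueError as err:
        raise ValueError(f"source: {err}") from err
    species = d.get("D_p_species_um2_s")
    return ModelConfig(fh=fh, kinetics=kin, growth=growth, grid=grid,
                       source=source, D_p_species=species,
                       seed=int(d.get("seed", 0)))


def model_config_to_dict(cfg: ModelConfig) -> Dict:
    """Inverse of :func:`model_config_from_dict` (lossless round trip)."""
    return {
        "interactions": {"chi_p": cfg.fh.chi_p, "chi_n": cfg.fh.chi_n,
                         "chi_np": cfg.fh.chi_np,
                         "lambda_if_um": cfg.fh.lambda_if,
                         "v_p": cfg.fh.v_p, "v_n": cfg.fh.v_n},
        "kinetics": {"D_p_um2_s": cfg.kinetics.D_p,
                     "D_n_um2_s": cfg.kinetics.D_n,
                     "k1_0_per_s": cfg.kinetics.k1_0,
                     "k_deg_per_s": cfg.kinetics.k_deg},
        "growth": {"gamma_per_hour": cfg.growth.gamma, "L0_um": cfg.growth.L0},
        "grid": {"N": cfg.grid.N, "dt_s": cfg.grid.dt,
                 "sample_stride": cfg.grid.sample_stride},
        "source": {"kind": cfg.source.kind,
                   "amplitude_k1": cfg.source.amplitude,
                   "extent_um": cfg.source.extent,
                   "k1_reduction": cfg.source.k1_reduction},
        "D_p_species_um2_s": (list(cfg.D_p_species)
                              if cfg.D_p_species is not None else None),
        "seed": cfg.seed,
    }


def synth_config_from_dict(d: Dict) -> SynthConfig:
    allowed = set(SynthConfig.__dataclass_fields__)
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
    return SynthConfig(**d)


# ---------------------------------------------------------------------------
# profiles <-> tidy tables

PROFILE_COLUMNS = ["cell_id", "frame", "channel", "bin", "position", "value",
                   "cell_length_um", "scaling"]


def profiles_to_frame(profiles: Sequence[Profile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        base = {
            "cell_id": p.meta.get("cell_id", -1),
            "frame": p.meta.get("frame", 0),
            "channel": p.channel,
            "cell_length_um": p.cell_length_um,
            "scaling": p.scaling,
        }
        extra = {k: v for k, v in p.meta.items()
                 if k not in ("cell_id", "frame") and np.isscalar(v)}
        for b, (pos, val) in enumerate(zip(p.positions, p.values)):
            rows.append({**base, "bin": b, "position": pos, "value": val,
                         **extra})
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> List[Profile]:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table lacks required columns: {missing}")
    out: List[Profile] = []
    meta_cols = [c for c in df.columns if c not in PROFILE_COLUMNS]
    for (cid, frame, channel), grp in df.groupby(
            ["cell_id", "frame", "channel"], sort=True):
        grp = grp.sort_values("bin")
        meta = {"cell_id": cid, "frame": frame}
        for c in meta_cols:
            meta[c] = grp[c].iloc[0]
        out.append(Profile(positions=grp["position"].to_numpy(),
                           values=grp["value"].to_numpy(),
                           cell_length_um=float(grp["cell_length_um"].iloc[0]),
                           scaling=str(grp["scaling"].iloc[0]),
                           channel=str(channel), meta=meta))
    return out


# ---------------------------------------------------------------------------
# trajectories and rasters

def save_trajectory(traj: Trajectory, path: PathLike) -> None:
    traj.to_frame().to_csv(path, index=False)


def load_trajectory(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_label_mask(labels: np.ndarray, path: PathLike) -> None:
    import tifffile
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


def read_label_mask(path: PathLike) -> np.ndarray:
    import tifffile
    return tifffile.imread(str(path))
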