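"""Cell-coordinate machinery: medial axis, pixel mapping, polarity, ages,
and nucleoid-cycle tracking.

Rod-shaped cells are reduced to a pole-to-pole medial axis with 0.1 px
resolution.  Every mask pixel is mapped to a (length, signed width)
coordinate pair; the relative length coordinate runs from the old pole (−1)
through the cell centre (0) to the new pole (+1) once polarity is assigned.
Lineage polarity follows the constriction-proximity rule: the daughter pole
closest to the mother's division site is the new pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label

__all__ = [
    "CellMask",
    "MedialAxis",
    "PixelMap",
    "NucleoidCycle",
    "medial_axis",
    "map_pixels",
    "assign_polarity",
    "assign_ages",
    "track_nucleoid_cycles",
    "DEFAULT_PIXEL_SIZE_UM",
]

DEFAULT_PIXEL_SIZE_UM = 0.066  # μm per pixel
AXIS_RESAMPLE_PX = 0.1         # medial-axis node spacing
SCAN_STEP_PX = 0.5             # skeleton-path resampling step

#: age-class propagation: (mother class, same polarity as mother) -> class
AGE_RULES: Dict[Tuple[int, bool], int] = {
    (1, True): 1, (1, False): 2,
    (2, False): 3, (2, True): 4,
    (3, True): 5, (3, False): 6,
}


@dataclass
class CellMask:
    """A segmented cell on an integer raster."""

    mask: np.ndarray                 # 2D bool
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame: int = 0
    cell_id: int = 0
    mother_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be a non-empty 2D boolean raster")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def is_connected(self) -> bool:
        return int(sk_label(self.mask).max()) == 1

    @property
    def centroid(self) -> Tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean()), float(ys.mean())


@dataclass
class MedialAxis:
    """Ordered sub-pixel medial-axis nodes, pole to pole.

    ``nodes`` are (x, y) coordinates spaced ``AXIS_RESAMPLE_PX`` apart in
    arc length; ``arc`` the cumulative arc length in px.  ``new_pole_at_end``
    records the polarity orientation (relative coordinate −1 at the start /
    old pole, +1 at the end / new pole).
    """

    nodes: np.ndarray               # (M, 2) float, (x, y)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    new_pole_at_end: bool = True

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[0] < 2:
            raise ValueError("axis needs at least two nodes")
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("arc length must be strictly increasing")
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_px(self) -> float:
        return float(self.arc[-1])

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size

    def flipped(self) -> "MedialAxis":
        return MedialAxis(self.nodes[::-1].copy(), self.pixel_size,
                          not self.new_pole_at_end)

    def relative_coordinate(self, arc_px: np.ndarray) -> np.ndarray:
        """Relative cell-length coordinate in [−1, 1] for arc positions."""
        return 2.0 * np.asarray(arc_px) / self.length_px - 1.0


@dataclass
class PixelMap:
    """Per-pixel cell coordinates and channel values."""

    xs: np.ndarray                # pixel x (col), px
    ys: np.ndarray                # pixel y (row), px
    length_coord: np.ndarray      # arc position of nearest axis node, px
    width_coord: np.ndarray      # signed distance to the axis, px
    channels: Dict[str, np.ndarray]
    axis_length_px: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    meta: Dict = field(default_factory=dict)

    @property
    def axis_length_um(self) -> float:
        return self.axis_length_px * self.pixel_size


# ---------------------------------------------------------------------------
# medial axis extraction

def _edt_interp(edt: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the distance transform at (x, y) points."""
    return ndimage.map_coordinates(edt, [pts[:, 1], pts[:, 0]], order=1,
                                   mode="constant", cval=0.0)


def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Ordered (x, y) coordinates of the skeleton's longest path.

    The morphological skeleton traces the locus of points most distant from
    the cell boundary; short side branches (spurs) are pruned by keeping the
    longest geodesic path through the skeleton graph (two breadth-first
    passes).
    """
    from skimage.morphology import skeletonize
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if xs.size < 2:
        raise ValueError("degenerate mask: empty skeleton")
    pix = set(zip(xs.tolist(), ys.tolist()))
    nbrs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0)]

    def bfs(start):
        seen = {start: None}
        queue = [start]
        last = start
        while queue:
            nxt = []
            for p in queue:
                for dx, dy in nbrs:
                    q = (p[0] + dx, p[1] + dy)
                    if q in pix and q not in seen:
                        seen[q] = p
                        nxt.append(q)
            if nxt:
                last = nxt[-1]
            queue = nxt
        return last, seen

    a, _ = bfs((int(xs[0]), int(ys[0])))
    b, seen = bfs(a)
    path = [b]
    while seen[path[-1]] is not None:
        path.append(seen[path[-1]])
    return np.asarray(path, dtype=float)


def _refine_to_ridge(edt: np.ndarray, nodes: np.ndarray,
                     reach: float = 1.2, n_off: int = 25,
                     iterations: int = 2) -> np.ndarray:
    """Move each node to the maximum of the interpolated EDT along its normal."""
    offsets = np.linspace(-reach, reach, n_off)
    out = nodes.copy()
    for _ in range(iterations):
        tang = np.gradient(out, axis=0)
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])
        norm /= np.maximum(np.linalg.norm(norm, axis=1, keepdims=True), 1e-12)
        for i in range(out.shape[0]):
            pts = out[i] + offsets[:, None] * norm[i]
            vals = _edt_interp(edt, pts)
            j = int(np.argmax(vals))
            if 0 < j < n_off - 1:  # parabolic sub-sample refinement
                denom = vals[j - 1] - 2 * vals[j] + vals[j + 1]
                shift = 0.5 * (vals[j - 1] - vals[j + 1]) / denom if denom != 0 else 0.0
                shift = np.clip(shift, -1.0, 1.0)
            else:
                shift = 0.0
            off = offsets[j] + shift * (offsets[1] - offsets[0])
            out[i] = out[i] + off * norm[i]
    return out


def _extrapolate_to_cap(edt: np.ndarray, start: np.ndarray,
                        direction: np.ndarray, step: float = 0.1,
                        ) -> List[np.ndarray]:
    """Extend a line from ``start`` along ``direction`` to the mask boundary.

    The sub-pixel boundary is taken where the interpolated distance
    transform falls to zero.
    """
    ny, nx = edt.shape
    d = direction / np.linalg.norm(direction)
    pts: List[np.ndarray] = []
    pos = start.astype(float)
    for _ in range(4000):
        pos = pos + step * d
        if not (0 <= pos[0] < nx - 1 and 0 <= pos[1] < ny - 1):
            break
        # EDT is measured to background pixel centres: the interpolated value
        # 0.5 sits on the true (sub-pixel) mask boundary
        if float(_edt_interp(edt, pos[None, :])[0]) <= 0.5:
            break
        pts.append(pos.copy())
    return pts


def medial_axis(cell: CellMask) -> MedialAxis:
    """Extract the pole-to-pole medial axis of a rod-shaped cell mask.

    Interior nodes are found by scanning along the ridge of the Euclidean
    distance transform with a 0.5 px step under a ±60° directionality
    constraint; the x and y node coordinates are then fitted separately as
    polynomials of the node number with degree d = max(1, floor(0.1·N − 5)),
    linearly extrapolated through the pole caps, and resampled to 0.1 px
    arc spacing.
    """
    if not cell.is_connected():
        raise ValueError("mask must be a single connected component")
    mask = cell.mask
    ys_m, xs_m = np.nonzero(mask)
    raw = _skeleton_path(mask)
    if raw.shape[0] < 4:
        raise ValueError("degenerate mask: too few medial-axis nodes")
    # resample the path at the node-scan step so the degree rule below sees
    # the node density it was written for
    seg = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    arc_raw = np.concatenate([[0.0], np.cumsum(seg)])
    # the skeleton's terminal stretch is rasterization-biased (spurs can run
    # up to ~half a cell width into the caps); trim it and let the cap
    # extrapolation cover the extra distance
    edt = ndimage.distance_transform_edt(mask)
    trim = min(max(2.5, 0.6 * float(edt.max())), 0.2 * arc_raw[-1])
    targets = np.arange(trim, arc_raw[-1] - trim + SCAN_STEP_PX / 2,
                        SCAN_STEP_PX)
    nodes = np.column_stack([np.interp(targets, arc_raw, raw[:, 0]),
                             np.interp(targets, arc_raw, raw[:, 1])])
    # refine each node to the sub-pixel ridge of the distance transform
    # along the local normal (the skeleton itself zigzags by up to ~0.7 px)
    nodes = _refine_to_ridge(edt, nodes)
    n_nodes = nodes.shape[0]
    if n_nodes < 4:
        raise ValueError("degenerate mask: too few medial-axis nodes")
    degree = max(1, int(np.floor(0.1 * n_nodes - 5)))
    idx = np.arange(n_nodes, dtype=float)
    px = np.polyfit(idx, nodes[:, 0], degree)
    py = np.polyfit(idx, nodes[:, 1], degree)
    fine = np.linspace(0.0, n_nodes - 1.0, max(4 * n_nodes, 64))
    curve = np.column_stack([np.polyval(px, fine), np.polyval(py, fine)])
    # linear extrapolation through the pole caps, aimed at the centroid of
    # each cap's pixels (those whose nearest curve point is the curve end).
    # The cap is mirror-symmetric about the axis, so its pixel centroid lies
    # on the axis — a sub-pixel-accurate direction anchor that averages out
    # both skeleton noise and rasterization bias.
    pix_xy = np.column_stack([xs_m, ys_m]).astype(float)
    tree_curve = cKDTree(curve)
    _, nearest = tree_curve.query(pix_xy)
    last = curve.shape[0] - 1

    def _cap_dir(end_idx: int) -> np.ndarray:
        cap = pix_xy[nearest == end_idx]
        e = curve[end_idx]
        if cap.shape[0] < 3:  # degenerate: fall back to the end segment
            other = curve[1] if end_idx == 0 else curve[-2]
            return e - other
        return cap.mean(axis=0) - e

    head = _extrapolate_to_cap(edt, curve[0], _cap_dir(0))
    tail = _extrapolate_to_cap(edt, curve[-1], _cap_dir(last))
    full = np.vstack([list(reversed(head)) + [curve[0]], curve[1:]])
    if tail:
        full = np.vstack([full, tail])
    # resample to uniform 0.1 px arc spacing
    seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    full = full[keep]
    seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, arc[-1] + AXIS_RESAMPLE_PX / 2, AXIS_RESAMPLE_PX)
    res = np.column_stack([np.interp(targets, arc, full[:, 0]),
                           np.interp(targets, arc, full[:, 1])])
    return MedialAxis(nodes=res, pixel_size=cell.pixel_size)


# ---------------------------------------------------------------------------
# pixel mapping

def map_pixels(cell: CellMask, axis: MedialAxis,
               channels: Optional[Dict[str, np.ndarray]] = None) -> PixelMap:
    """Map every mask pixel to (length, signed width) cell coordinates.

    The length coordinate is the arc position of the nearest axis node; the
    width is the Euclidean distance to that node, signed by a cross product
    at the projection P so the two sides of the sagittal plane get opposite
    signs.  The sign uses the local axis tangent, cross(t̂, P→pixel): a
    centroid-based reference (P→centroid) identifies the side only through
    the centroid's off-axis offset and degenerates for straight cells.
    """
    ys, xs = np.nonzero(cell.mask)
    pix = np.column_stack([xs, ys]).astype(float)
    tree = cKDTree(axis.nodes)
    dist, idx = tree.query(pix)
    proj = axis.nodes[idx]
    tang = np.gradient(axis.nodes, axis=0)[idx]
    v_pl = pix - proj
    cross = tang[:, 0] * v_pl[:, 1] - tang[:, 1] * v_pl[:, 0]
    sign = np.sign(cross)
    chan_vals = {}
    if channels:
        for name, img in channels.items():
            chan_vals[name] = np.asarray(img, dtype=float)[ys, xs]
    return PixelMap(xs=xs.astype(float), ys=ys.astype(float),
                    length_coord=axis.arc[idx], width_coord=dist * sign,
                    channels=chan_vals, axis_length_px=axis.length_px,
                    pixel_size=cell.pixel_size,
                    meta={"cell_id": cell.cell_id, "frame": cell.frame})


# ---------------------------------------------------------------------------
# polarity and age classes

def assign_polarity(lineage: pd.DataFrame,
                    root_polarity: Optional[Dict[int, str]] = None,
                    ) -> pd.DataFrame:
    """Determine each cell's new pole from the mother's constriction site.

    ``lineage`` must carry columns ``cell_id``, ``mother_id`` (NaN for
    roots) and the cell's interval along the channel/axis at birth
    (``pos_lo``, ``pos_hi``).  The daughter pole closer to the mother's
    division site — the boundary shared by the two sisters — becomes the
    new pole.  Returns a copy with ``new_pole_side`` ∈ {"lo", "hi", "unknown"}.
    Root cells take ``root_polarity`` if given, else are flagged unknown.
    """
    for col in ("cell_id", "mother_id", "pos_lo", "pos_hi"):
        if col not in lineage.columns:
            raise ValueError(f"lineage table lacks required column {col!r}")
    df = lineage.copy()
    sides = []
    by_id = df.set_index("cell_id")
    for _, row in df.iterrows():
        mid = row["mother_id"]
        if pd.isna(mid):
            side = (root_polarity or {}).get(row["cell_id"], "unknown")
            sides.append(side)
            continue
        sisters = df[(df["mother_id"] == mid) & (df["cell_id"] != row["cell_id"])]
        if len(sisters) == 0:
            sides.append("unknown")
            continue
        sis = sisters.iloc[0]
        # division site = the edge shared by the sisters
        gaps = {
            "lo": abs(row["pos_lo"] - sis["pos_hi"]),
            "hi": abs(row["pos_hi"] - sis["pos_lo"]),
        }
        sides.append(min(gaps, key=gaps.get))
    df["new_pole_side"] = sides
    return df


def assign_ages(lineage: pd.DataFrame) -> pd.DataFrame:
    """Assign age/lineage classes 1–6 relative to the oldest mother cells.

    Root cells are the oldest mothers (class 1).  A daughter with the same
    polarity as its mother keeps class 1 mothers' class; the opposite-
    polarity daughter of a class-1 mother founds class 2; class-2 mothers'
    daughters found classes 3 (opposite polarity) and 4 (same); class-3
    mothers' daughters found classes 5 (same) and 6 (opposite).  Deeper
    branches are labelled 0 ("beyond-6"); unlinked cells with unknown
    polarity get class −1 (undefined).
    """
    if "new_pole_side" not in lineage.columns:
        raise ValueError("assign polarity before ages")
    df = lineage.copy()
    classes: Dict[int, int] = {}
    by_id = {int(r["cell_id"]): r for _, r in df.iterrows()}

    def resolve(cid: int) -> int:
        if cid in classes:
            return classes[cid]
        row = by_id[cid]
        mid = row["mother_id"]
        if pd.isna(mid):
            classes[cid] = 1
            return 1
        mother = by_id.get(int(mid))
        if mother is None or row["new_pole_side"] == "unknown" \
                or mother["new_pole_side"] == "unknown":
            classes[cid] = -1
            return -1
        mclass = resolve(int(mid))
        if mclass in (-1, 0):
            classes[cid] = 0 if mclass == 0 else -1
            return classes[cid]
        same = row["new_pole_side"] == mother["new_pole_side"]
        classes[cid] = AGE_RULES.get((mclass, same), 0)
        return classes[cid]

    df["age_class"] = [resolve(int(c)) for c in df["cell_id"]]
    return df


# ---------------------------------------------------------------------------
# nucleoid-cycle tracking

@dataclass
class NucleoidCycle:
    """A tracked nucleoid from the end of one splitting to the end of its own.

    ``observations`` are (frame, cell_id, centroid_rel) triples with the
    centroid in polarity-oriented relative coordinates.  The inheritance
    group is ±1 when the nucleoid was inherited from the mother's new pole
    (opposite-polarity daughter) and ±2 from the old pole; the sign encodes
    the daughter's own orientation (+ for new pole on the "hi" side).
    ``complete`` is True when the closing split was observed.
    """

    observations: List[Tuple[int, int, float]]
    complete: bool = False
    inheritance_group: Optional[int] = None
    spans_division: bool = False
    #: frame of the closing splitting event (first frame with two objects)
    closing_frame: Optional[int] = None

    @property
    def start_frame(self) -> int:
        return self.observations[0][0]

    @property
    def end_frame(self) -> int:
        if self.closing_frame is not None:
            return self.closing_frame
        return self.observations[-1][0]


def _cell_frames(obs: pd.DataFrame) -> Dict[int, List[float]]:
    out: Dict[int, List[float]] = {}
    for frame, grp in obs.groupby("frame"):
        out[int(frame)] = sorted(grp["centroid_rel"].tolist())
    return out


def track_nucleoid_cycles(observations: pd.DataFrame,
                          lineage: pd.DataFrame) -> List[NucleoidCycle]:
    """Track nucleoid objects through splitting events and across division.

    ``observations``: tidy table (cell_id, frame, centroid_rel) with one row
    per segmented nucleoid object, centroids in polarity-oriented relative
    coordinates (−1 old pole … +1 new pole).  ``lineage`` must carry
    ``cell_id``, ``mother_id`` and ``new_pole_side``.

    Within a cell, objects are matched frame-to-frame by position order; a
    1→2 count increase closes the current cycle (end of splitting) and opens
    one cycle per emerging sister.  At division, a mother's nucleoid at the
    new-pole quarter continues in the opposite-polarity daughter (group ±1)
    and the old-pole nucleoid in the same-polarity daughter (group ±2),
    each re-centred at the daughter's mid-cell.  Cycles cut short by the end
    of the recording or by tracking gaps are returned with
    ``complete=False``.
    """
    if "new_pole_side" not in lineage.columns:
        raise ValueError("lineage needs polarity (run assign_polarity first)")
    lin = lineage.set_index("cell_id")
    children: Dict[int, List[int]] = {}
    for cid, row in lin.iterrows():
        if not pd.isna(row["mother_id"]):
            children.setdefault(int(row["mother_id"]), []).append(int(cid))

    cycles: List[NucleoidCycle] = []

    def process_cell(cid: int, carried: Dict[str, dict]) -> None:
        """Track within one cell; ``carried`` maps 'new'/'old'-pole inherited
        open cycles from the mother into this cell."""
        sub = observations[observations["cell_id"] == cid]
        frames = _cell_frames(sub)
        if not frames:
            return
        order = sorted(frames)
        # open tracks: list of dicts {obs: [...], complete-flag closed later}
        tracks: List[dict] = []
        inherited = carried.get("track")
        if inherited is not None:
            tracks = [inherited]
        prev_count = len(tracks) if tracks else None
        for f in order:
            cents = frames[f]
            count = len(cents)
            if prev_count is None or not tracks:
                tracks = [{"obs": [(f, cid, c)], "known_start": False}
                          for c in cents]
            elif count == len(tracks):
                trk_pos = [t["obs"][-1][2] for t in tracks]
                for t, c in zip([t for _, t in sorted(
                        zip(trk_pos, tracks), key=lambda z: z[0])], cents):
                    t["obs"].append((f, cid, c))
            elif count > len(tracks) and len(tracks) == 1:
                # end of a splitting event: close the mother cycle …
                t = tracks[0]
                cycles.append(NucleoidCycle(
                    observations=t["obs"],
                    complete=t.get("known_start", False),
                    inheritance_group=t.get("group"),
                    spans_division=t.get("spans", False),
                    closing_frame=f))
                # … and open one cycle per emerging sister
                tracks = [{"obs": [(f, cid, c)], "known_start": True}
                          for c in cents]
            else:
                # gap or fusion: emit what we have as incomplete
                for t in tracks:
                    cycles.append(NucleoidCycle(
                        observations=t["obs"], complete=False,
                        inheritance_group=t.get("group"),
                        spans_division=t.get("spans", False)))
                tracks = [{"obs": [(f, cid, c)], "known_start": False}
                          for c in cents]
            prev_count = count
        # division: hand surviving tracks to the daughters
        kids = children.get(cid, [])
        if kids and tracks:
            my_side = lin.loc[cid, "new_pole_side"]
            for kid in kids:
                kid_side = lin.loc[kid, "new_pole_side"]
                # opposite-polarity daughters inherit the mother's new pole
                want_new_pole = kid_side != my_side
                if len(tracks) == 1:
                    # a single surviving nucleoid goes to the matching half
                    toward_new = tracks[0]["obs"][-1][2] > 0
                    if toward_new != want_new_pole:
                        process_cell(kid, {})
                        continue
                    cand = tracks[0]
                else:
                    cand = max(tracks, key=lambda t: t["obs"][-1][2]) \
                        if want_new_pole \
                        else min(tracks, key=lambda t: t["obs"][-1][2])
                group = (1 if want_new_pole else 2) * (1 if kid_side == "hi" else -1)
                carried_track = {"obs": list(cand["obs"]),
                                 "known_start": cand.get("known_start", False),
                                 "group": group, "spans": True}
                process_cell(kid, {"track": carried_track})
            return
        for kid in kids:
            process_cell(kid, {})
        if not kids:
            for t in tracks:
                cycles.append(NucleoidCycle(
                    observations=t["obs"], complete=False,
                    inheritance_group=t.get("group"),
                    spans_division=t.get("spans", False)))

    roots = [int(c) for c in lin.index[lin["mother_id"].isna()]]
    for root in roots:
        process_cell(root, {})
    return cycles
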