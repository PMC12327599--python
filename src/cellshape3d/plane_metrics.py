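"""Per-z-plane 2D metrics of each cell, supplementing the 3D measures.

Area and perimeter are pixel counts (perimeter counts exposed pixel edges,
consistent with the 3D surface estimator, hence an overestimate of smooth
perimeters).  Orientation and anisotropy come from the 2D second-moment
ellipse; anisotropy is the major/minor axis ratio, ≥ 1 by construction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .segmentation import CellMask
from .topology import TissueTopology

__all__ = ["PlaneMetrics", "per_plane_metrics", "cell_plane_metrics",
           "neighbour_count_2d_vs_3d"]


@dataclasses.dataclass
class PlaneMetrics:
    cell_id: int
    z: int
    area: float
    perimeter: float
    orientation: float  # degrees from the x axis, (−90°, 90°]
    anisotropy: float
    major_axis: float  # µm


def _slice_at(cell: CellMask, z: int) -> np.ndarray:
    zl = z - cell.offset[0]
    if zl < 0 or zl >= cell.mask.shape[0] or not cell.mask[zl].any():
        raise ValueError(f"cell {cell.cell_id} does not occupy plane z={z}")
    return cell.mask[zl]


def per_plane_metrics(cell: CellMask, z: int, voxel_size) -> PlaneMetrics:
    """2D shape metrics of one cell's slice at global plane index ``z``."""
    px = float(voxel_size) if np.isscalar(voxel_size) else float(voxel_size[-1])
    sl = _slice_at(cell, z)
    n = int(sl.sum())
    area = n * px * px
    exposed = 0
    padded = np.pad(sl, 1)  # count boundary pixel edges as exposed
    for ax in range(2):
        m = np.moveaxis(padded, ax, 0)
        exposed += int((m[:-1] & ~m[1:]).sum()) + int((m[1:] & ~m[:-1]).sum())
    perimeter = exposed * px

    ys, xs = np.nonzero(sl)
    pts = np.stack([xs, ys], axis=1).astype(float)
    if n == 1:
        return PlaneMetrics(cell.cell_id, z, area, perimeter, 0.0, 1.0, px)
    centred = pts - pts.mean(axis=0)
    # second moments with the unit-square pixel term, as for an image ellipse
    cov = centred.T @ centred / n + np.eye(2) / 12.0
    vals, vecs = np.linalg.eigh(cov)
    major_v, minor_v = float(vals[1]), float(vals[0])
    vx, vy = vecs[0, 1], vecs[1, 1]
    ang = math.degrees(math.atan2(vy, vx))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    if np.isclose(major_v, minor_v):
        ang = 0.0
    anisotropy = math.sqrt(major_v / minor_v) if minor_v > 0 else float("inf")
    major_axis = 4.0 * math.sqrt(major_v) * px  # full axis of the moment ellipse
    return PlaneMetrics(cell.cell_id, z, area, perimeter, ang, anisotropy, major_axis)


def cell_plane_metrics(cell: CellMask, voxel_size) -> list[PlaneMetrics]:
    """One :class:`PlaneMetrics` row per occupied plane of the cell."""
    z0 = cell.offset[0]
    out = []
    for zl in range(cell.mask.shape[0]):
        if cell.mask[zl].any():
            out.append(per_plane_metrics(cell, z0 + zl, voxel_size))
    return out


def neighbour_count_2d_vs_3d(topo: TissueTopology) -> dict[int, tuple[int, int]]:
    """Per cell: (in-plane neighbour count at the apical-most occupied
    plane, total 3D neighbour count).

    The apical proxy is the highest occupied z index.  For prisms the two
    counts agree; scutoid-like cells have strictly more 3D neighbours than
    any single plane shows.
    """
    out: dict[int, tuple[int, int]] = {}
    for cid, ct in topo.cells.items():
        if ct.plane_neighbours:
            apical = max(ct.plane_neighbours)
            n2d = len(ct.plane_neighbours[apical])
        else:
            n2d = 0
        out[cid] = (n2d, len(ct.neighbours))
    return out
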