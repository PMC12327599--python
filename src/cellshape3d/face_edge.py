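"""Face and edge geometry: SVD plane fits, flatness, projected footprints,
per-plane face segments, junction tortuosity and cell twist.

A face's voxel cloud is projected onto its best-fitting plane by singular
value decomposition; *flatness* is the variance of the coordinates along
the fitted normal (0 for a perfectly planar face).  Projected area and
perimeter are read off a rasterisation of the in-plane coordinates at
voxel resolution, so a flat axis-aligned wall reproduces its raw pixel
counts; strongly bent faces are underestimated by the projection.  Edge
(junction) polylines give tortuosity in the same 1 − l_short/l_real form
as cell straightness, and the rotation of a cell's junctions about its
centreline traces apico-basal twist.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cell_metrics import Centreline
from .topology import CellTopology, EdgeRecord, FaceRecord

__all__ = [
    "FacePlaneFit",
    "EdgeGeometry",
    "TwistProfile",
    "fit_face_plane",
    "face_area_perimeter",
    "face_per_plane",
    "edge_geometry",
    "compute_twist",
]


@dataclasses.dataclass
class FacePlaneFit:
    face_id: int
    centroid: np.ndarray  # (3,) µm, (z, y, x)
    basis: np.ndarray  # (2, 3) orthonormal in-plane directions
    normal: np.ndarray  # (3,)
    singular_values: np.ndarray  # (3,) descending
    projected: np.ndarray  # (N, 2) in-plane coordinates, µm
    flatness: float  # variance along the normal, µm²


@dataclasses.dataclass
class EdgeGeometry:
    edge_id: int
    polyline: np.ndarray  # (n, 3) per-plane mean positions, µm
    real_length: float
    straight_length: float
    tortuosity: float  # NaN for single-plane edges
    z_min: int
    z_max: int


@dataclasses.dataclass
class TwistProfile:
    cell_id: int
    planes: np.ndarray  # global z indices carrying a rotation estimate
    rotation: np.ndarray  # mean unwrapped rotation per plane, degrees
    total_twist: float  # degrees, signed (right-handed about +z)
    twist_rate: float  # degrees per µm of centreline
    n_edges: int


def _voxel_edge(voxel_size) -> float:
    return float(voxel_size) if np.isscalar(voxel_size) else float(voxel_size[-1])


def fit_face_plane(face: FaceRecord, voxel_size=1.0) -> FacePlaneFit:
    """Best-fitting plane of the face pixel cloud by SVD.

    The two leading right singular vectors span the plane; the third is
    the normal.  Flatness is the population variance of the coordinates
    along the normal — 0 exactly when all pixels are coplanar.
    """
    px = _voxel_edge(voxel_size)
    pts = face.pixels.astype(float) * px
    if len(pts) < 3:
        raise ValueError(f"face {face.face_id}: plane fit needs >= 3 pixels")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError(f"face {face.face_id}: pixels are collinear")
    flatness = float(s[2] ** 2 / len(pts))
    return FacePlaneFit(
        face_id=face.face_id,
        centroid=centroid,
        basis=vt[:2],
        normal=vt[2],
        singular_values=s,
        projected=centred @ vt[:2].T,
        flatness=flatness,
    )


def face_area_perimeter(fit: FacePlaneFit, voxel_size=1.0) -> tuple[float, float]:
    """Area and perimeter of the projected planar footprint.

    The in-plane coordinates are binned at voxel resolution; area counts
    occupied bins, perimeter counts exposed bin edges.  Both are measured
    in the fitted plane, so folded faces come out smaller than their
    unfolded extent.
    """
    px = _voxel_edge(voxel_size)
    bins = np.floor((fit.projected - fit.projected.min(axis=0)) / px + 0.5).astype(int)
    shape = bins.max(axis=0) + 1
    grid = np.zeros(shape, dtype=bool)
    grid[bins[:, 0], bins[:, 1]] = True
    area = float(grid.sum()) * px * px
    grid = np.pad(grid, 1)  # boundary bin edges are exposed too
    exposed = 0
    for ax in range(2):
        m = np.moveaxis(grid, ax, 0)
        exposed += int((m[:-1] & ~m[1:]).sum()) + int((m[1:] & ~m[:-1]).sum())
    return area, float(exposed) * px


def face_per_plane(
    face: FaceRecord, voxel_size=1.0
) -> list[tuple[int, float, float]]:
    """Per z-plane (z, length, angle) of the face's pixel curve.

    Within each plane the pixels are binned along their principal 2D
    direction (unit-width bins), the per-bin mean positions form a
    polyline, and length is that polyline's arc length — so a straight
    two-voxel-thick wall of width w reports w−1 unit steps.  Angle is the
    principal direction's xy orientation in (−90°, 90°]; single-bin planes
    report zero length and a NaN angle.
    """
    px = _voxel_edge(voxel_size)
    out: list[tuple[int, float, float]] = []
    for z in np.unique(face.pixels[:, 0]):
        pts = face.pixels[face.pixels[:, 0] == z][:, 1:].astype(float)  # (y, x)
        if len(pts) == 1:
            out.append((int(z), 0.0, float("nan")))
            continue
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]  # (dy, dx)
        proj = centred @ direction
        slabs = np.floor(proj - proj.min()).astype(int)
        order = np.unique(slabs)
        if len(order) == 1:
            out.append((int(z), 0.0, float("nan")))
            continue
        poly = np.stack([pts[slabs == s].mean(axis=0) for s in order])
        length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()) * px
        ang = math.degrees(math.atan2(direction[0], direction[1]))
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        out.append((int(z), length, ang))
    return out


def edge_geometry(edge: EdgeRecord, voxel_size=1.0) -> EdgeGeometry:
    """Junction polyline (per-plane mean of edge pixels) and tortuosity.

    Single-plane edges are degenerate: lengths 0, tortuosity NaN.  Partial
    z-extent is expected for junctions of scutoid cells.
    """
    px = _voxel_edge(voxel_size)
    zs = np.unique(edge.pixels[:, 0])
    poly = np.stack(
        [edge.pixels[edge.pixels[:, 0] == z].mean(axis=0) for z in zs]
    ).astype(float) * px
    if len(poly) < 2:
        return EdgeGeometry(edge.edge_id, poly, 0.0, 0.0, float("nan"),
                            edge.z_min, edge.z_max)
    real = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
    straight = float(np.linalg.norm(poly[-1] - poly[0]))
    tort = 1.0 - straight / real if real > 0 else float("nan")
    return EdgeGeometry(edge.edge_id, poly, real, straight, tort,
                        edge.z_min, edge.z_max)


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    """Cumulative smallest signed differences, first element 0."""
    diffs = np.diff(angles)
    diffs = (diffs + 180.0) % 360.0 - 180.0
    return np.concatenate([[0.0], np.cumsum(diffs)])


def compute_twist(
    cell: CellTopology,
    centreline: Centreline,
    edges: list[EdgeGeometry],
    voxel_size=1.0,
    min_edge_planes: int = 3,
) -> TwistProfile | None:
    """Signed apico-basal twist of a cell from the rotation of its
    junctions about the centreline.

    For every incident edge and plane, the xy-angle of the vector from the
    centreline point to the edge position is taken (right-handed about
    +z); each edge's angle profile is unwrapped along z relative to its
    first plane, profiles are averaged per plane, and the total twist is
    the mean rotation at the last plane.  Returns ``None`` when fewer than
    two incident edges span ``min_edge_planes`` planes.
    """
    px = _voxel_edge(voxel_size)
    # centreline points indexed by global plane: points are per-plane means,
    # so their z component identifies the plane
    centre_by_z = {int(round(p[0] / px)): p for p in centreline.points}
    profiles: list[dict[int, float]] = []
    for eg in edges:
        if len(eg.polyline) < min_edge_planes:
            continue
        angles: dict[int, float] = {}
        for p in eg.polyline:
            z = int(round(p[0] / px))
            if z not in centre_by_z:
                continue
            c = centre_by_z[z]
            dy, dx = p[1] - c[1], p[2] - c[2]
            angles[z] = math.degrees(math.atan2(dy, dx))
        if len(angles) < min_edge_planes:
            continue
        zs = sorted(angles)
        unwrapped = _unwrap_deg(np.array([angles[z] for z in zs]))
        profiles.append(dict(zip(zs, unwrapped)))
    if len(profiles) < 2:
        return None
    planes = sorted(set().union(*[p.keys() for p in profiles]))
    rotation = np.array(
        [np.mean([p[z] for p in profiles if z in p]) for z in planes]
    )
    total = float(rotation[-1] - rotation[0])
    rate = total / centreline.l_real if centreline.l_real > 0 else float("nan")
    return TwistProfile(
        cell_id=cell.cell_id,
        planes=np.asarray(planes),
        rotation=rotation,
        total_twist=total,
        twist_rate=rate,
        n_edges=len(profiles),
    )
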