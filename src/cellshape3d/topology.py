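"""Tissue topology extraction from a labelled volume.

Neighbourhoods are found by the dilate-and-multiply rule: a cell's binary
mask is dilated by one voxel and overlaid on the label image — the labels
remaining under the dilated shell are the touching cells.  Pairwise
intersections of dilated masks give *faces* (cell–cell contact surfaces);
triple intersections give *edges* (the junction curves where three cells
meet).  The result is assembled into a region adjacency graph (RAG) and
three linked tables (cell / face / edge) in a half-face convention: each
contact surface is stored once per incident cell, with mutual mirror
references.

All operations assume an isotropic labelled volume and 6-connectivity
(face adjacency): cells that meet only at a voxel corner or edge are not
neighbours, which keeps the RAG free of spurious diagonal contacts.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import ndimage

from .segmentation import CellMask, LabeledVolume, decompose_cells

__all__ = [
    "FaceRecord",
    "EdgeRecord",
    "CellTopology",
    "TissueTopology",
    "dilate_mask",
    "find_neighbours",
    "voxel_pair_adjacency",
    "build_rag",
    "find_face_pixels",
    "find_edge_pixels",
    "build_topology_tables",
    "detect_scutoid",
]

#: 6-connected (face adjacency) structuring elements.
STRUCT_3D = ndimage.generate_binary_structure(3, 1)
STRUCT_2D = ndimage.generate_binary_structure(2, 1)

#: A cell is a border cell when at least this fraction of its lateral
#: (in-plane) one-voxel shell is background or outside the volume.
BORDER_BACKGROUND_FRACTION = 0.05

#: Planes where a cell has fewer voxels than this are ignored by scutoid
#: detection: cell tips produce spurious neighbour-set changes.
MIN_PLANE_VOXELS = 4


def dilate_mask(cell: CellMask) -> CellMask:
    """Binary dilation by one voxel with the 6-connected element."""
    mask = cell.mask if cell.padded else np.pad(cell.mask, 1)
    offset = cell.offset if cell.padded else tuple(o - 1 for o in cell.offset)
    dilated = ndimage.binary_dilation(mask, structure=STRUCT_3D)
    return CellMask(cell_id=cell.cell_id, mask=dilated, offset=offset, padded=False)


def _overlap(cell: CellMask, shape: tuple[int, int, int]):
    """Slices mapping the mask into the parent array, clipping the margin.

    Returns ``(vol_slices, mask_slices)`` or ``None`` if disjoint.
    """
    vs, ms = [], []
    for ax in range(3):
        lo = cell.offset[ax]
        hi = lo + cell.mask.shape[ax]
        v0, v1 = max(lo, 0), min(hi, shape[ax])
        if v0 >= v1:
            return None
        vs.append(slice(v0, v1))
        ms.append(slice(v0 - lo, v1 - lo))
    return tuple(vs), tuple(ms)


def find_neighbours(vol: LabeledVolume, cell: CellMask) -> set[int]:
    """IDs of cells whose voxels lie under the 1-voxel dilated shell."""
    first = cell.coords()[0]
    if not (
        np.all(first >= 0)
        and np.all(first < np.asarray(vol.shape))
        and vol.labels[tuple(first)] == cell.cell_id
    ):
        raise ValueError(f"cell id {cell.cell_id} not found at its offset in the volume")
    dil = dilate_mask(cell)
    sl = _overlap(dil, vol.shape)
    assert sl is not None
    vol_sl, mask_sl = sl
    shell = dil.mask[mask_sl] & ~cell.mask[mask_sl]
    labels = vol.labels[vol_sl][shell]
    ids = np.unique(labels)
    return {int(i) for i in ids if i != 0 and i != cell.cell_id}


def voxel_pair_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    """Exhaustive 6-connected differing-label voxel-pair scan.

    Vectorised sweep over the three axes; every unordered pair of nonzero
    labels that share a voxel face is reported.  Algorithmically independent
    of the dilate-and-multiply route and used to cross-check it.
    """
    pairs: set[tuple[int, int]] = set()
    for ax in range(3):
        a = np.moveaxis(labels, ax, 0)[:-1]
        b = np.moveaxis(labels, ax, 0)[1:]
        touching = (a != b) & (a > 0) & (b > 0)
        if not touching.any():
            continue
        stacked = np.stack([a[touching], b[touching]])
        lo, hi = stacked.min(axis=0), stacked.max(axis=0)
        uniq = np.unique(np.stack([lo, hi], axis=1), axis=0)
        pairs.update((int(i), int(j)) for i, j in uniq)
    return pairs


def build_rag(
    vol: LabeledVolume, cells: list[CellMask] | None = None
) -> nx.Graph:
    """Region adjacency graph: nodes = cell ids, links = contacts."""
    if cells is None:
        cells = decompose_cells(vol)
    graph = nx.Graph()
    graph.add_nodes_from(cell.cell_id for cell in cells)
    for cell in cells:
        for nb in find_neighbours(vol, cell):
            graph.add_edge(cell.cell_id, nb)
    return graph


def _dilated_intersection(cells: tuple[CellMask, ...]) -> np.ndarray:
    """Global (z, y, x) voxel coordinates common to all dilated masks."""
    dils = [dilate_mask(c) for c in cells]
    lo = np.max([d.offset for d in dils], axis=0)
    hi = np.min([np.asarray(d.offset) + d.mask.shape for d in dils], axis=0)
    if np.any(hi <= lo):
        return np.empty((0, 3), dtype=np.int64)
    inter = None
    for d in dils:
        sl = tuple(
            slice(int(lo[ax] - d.offset[ax]), int(hi[ax] - d.offset[ax]))
            for ax in range(3)
        )
        crop = d.mask[sl]
        inter = crop if inter is None else inter & crop
    return np.argwhere(inter) + lo


def find_face_pixels(cell_i: CellMask, cell_j: CellMask) -> np.ndarray:
    """Contact-surface voxels of a cell pair: the dilated-mask intersection.

    Empty array when the cells are not in contact.  Symmetric in (i, j).
    """
    if cell_i.cell_id == cell_j.cell_id:
        raise ValueError("face requires two distinct cells")
    return _dilated_intersection((cell_i, cell_j))


def find_edge_pixels(
    cell_i: CellMask, cell_j: CellMask, cell_k: CellMask
) -> np.ndarray:
    """Junction voxels where three cells meet: the triple intersection.

    For scutoid cells the junction may span only part of the cells'
    z-extent; a partial result is valid.
    """
    ids = {cell_i.cell_id, cell_j.cell_id, cell_k.cell_id}
    if len(ids) != 3:
        raise ValueError("edge requires three distinct cells")
    return _dilated_intersection((cell_i, cell_j, cell_k))


@dataclasses.dataclass
class FaceRecord:
    """Half-face: one cell's view of a contact surface with a neighbour."""

    face_id: int
    cell_id: int
    opposite_cell_id: int
    pixels: np.ndarray  # (N, 3) global voxel coordinates
    mirror_face_id: int


@dataclasses.dataclass
class EdgeRecord:
    """A three-cell junction; ``cells`` stored as a sorted triplet."""

    edge_id: int
    cells: tuple[int, int, int]
    pixels: np.ndarray
    z_min: int
    z_max: int
    face_ids: tuple[int, ...] = ()  # incident half-faces (all six mirrors)


@dataclasses.dataclass
class CellTopology:
    cell_id: int
    neighbours: frozenset[int]
    plane_neighbours: dict[int, frozenset[int]]  # global z -> in-plane contacts
    plane_voxels: dict[int, int]  # global z -> voxel count in that plane
    face_ids: list[int]
    edge_ids: list[int]
    is_border: bool


@dataclasses.dataclass
class TissueTopology:
    """Linked cell / face / edge tables plus the connectivity graph."""

    graph: nx.Graph
    cells: dict[int, CellTopology]
    faces: dict[int, FaceRecord]
    edges: dict[int, EdgeRecord]
    masks: dict[int, CellMask]

    def cell_table(self):
        import pandas as pd

        rows = []
        for c in sorted(self.cells):
            ct = self.cells[c]
            rows.append(
                {
                    "cell_id": c,
                    "n_neighbours": len(ct.neighbours),
                    "n_faces": len(ct.face_ids),
                    "n_edges": len(ct.edge_ids),
                    "is_border": ct.is_border,
                }
            )
        return pd.DataFrame(rows)

    def face_table(self):
        import pandas as pd

        rows = []
        for f in sorted(self.faces):
            fr = self.faces[f]
            rows.append(
                {
                    "face_id": f,
                    "cell_id": fr.cell_id,
                    "opposite_cell_id": fr.opposite_cell_id,
                    "mirror_face_id": fr.mirror_face_id,
                    "n_pixels": len(fr.pixels),
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self):
        import pandas as pd

        rows = []
        for e in sorted(self.edges):
            er = self.edges[e]
            rows.append(
                {
                    "edge_id": e,
                    "cell_1": er.cells[0],
                    "cell_2": er.cells[1],
                    "cell_3": er.cells[2],
                    "z_min": er.z_min,
                    "z_max": er.z_max,
                    "n_pixels": len(er.pixels),
                }
            )
        return pd.DataFrame(rows)


def _plane_scan(vol: LabeledVolume, cell: CellMask):
    """Per-plane in-plane neighbours, voxel counts and lateral border stats.

    In-plane contacts use 4-connectivity, consistent with the 3D
    6-connectivity choice; the apical/basal caps (contacts along z) are not
    lateral contacts and are excluded by construction, matching the rule
    that the top and bottom of a monolayer cell are not faces.
    """
    sl = _overlap(cell, vol.shape)
    assert sl is not None
    vol_sl, mask_sl = sl
    labels_crop = vol.labels[vol_sl]
    mask_crop = cell.mask[mask_sl]
    z0 = vol_sl[0].start
    plane_nbrs: dict[int, frozenset[int]] = {}
    plane_vox: dict[int, int] = {}
    shell_total = 0
    shell_bg = 0
    touches_xy_border = False
    ny, nx_ = vol.shape[1], vol.shape[2]
    y0, x0 = vol_sl[1].start, vol_sl[2].start
    for zl in range(mask_crop.shape[0]):
        slice2d = mask_crop[zl]
        n_vox = int(slice2d.sum())
        if n_vox == 0:
            continue
        z = z0 + zl
        plane_vox[z] = n_vox
        dil = ndimage.binary_dilation(slice2d, structure=STRUCT_2D)
        shell = dil & ~slice2d
        vals = labels_crop[zl][shell]
        nbrs = np.unique(vals)
        plane_nbrs[z] = frozenset(
            int(v) for v in nbrs if v != 0 and v != cell.cell_id
        )
        shell_total += int(shell.sum())
        shell_bg += int((vals == 0).sum())
        # dilation escaping the y/x bounds of the parent array counts as
        # background contact (segmentation edge)
        ys, xs = np.nonzero(slice2d)
        if (
            (ys.min() + y0) == 0
            or (ys.max() + y0) == ny - 1
            or (xs.min() + x0) == 0
            or (xs.max() + x0) == nx_ - 1
        ):
            touches_xy_border = True
    frac = shell_bg / shell_total if shell_total else 1.0
    is_border = touches_xy_border or frac >= BORDER_BACKGROUND_FRACTION
    return plane_nbrs, plane_vox, is_border


def build_topology_tables(
    vol: LabeledVolume, cells: list[CellMask] | None = None
) -> TissueTopology:
    """Decompose a labelled volume into linked cell, face and edge tables.

    Faces are stored as half-faces (one row per ordered cell→neighbour
    pair) sharing one pixel set, with mutual mirror ids.  Edges are
    enumerated once per sorted triplet of mutually adjacent cells and kept
    when the triple intersection is nonempty; each edge cross-references
    the six incident half-faces.  Cells at the lateral segmentation edge
    are flagged: their faces and edges are only partially extracted.
    """
    if cells is None:
        cells = decompose_cells(vol)
    masks = {c.cell_id: c for c in cells}
    graph = build_rag(vol, cells)

    cell_topo: dict[int, CellTopology] = {}
    for c in cells:
        plane_nbrs, plane_vox, is_border = _plane_scan(vol, c)
        cell_topo[c.cell_id] = CellTopology(
            cell_id=c.cell_id,
            neighbours=frozenset(graph.neighbors(c.cell_id)),
            plane_neighbours=plane_nbrs,
            plane_voxels=plane_vox,
            face_ids=[],
            edge_ids=[],
            is_border=is_border,
        )

    faces: dict[int, FaceRecord] = {}
    pair_to_faces: dict[tuple[int, int], tuple[int, int]] = {}
    fid = 0
    for i, j in sorted(tuple(sorted(e)) for e in graph.edges):
        pixels = find_face_pixels(masks[i], masks[j])
        f_ij, f_ji = fid, fid + 1
        faces[f_ij] = FaceRecord(f_ij, i, j, pixels, mirror_face_id=f_ji)
        faces[f_ji] = FaceRecord(f_ji, j, i, pixels, mirror_face_id=f_ij)
        pair_to_faces[(i, j)] = (f_ij, f_ji)
        cell_topo[i].face_ids.append(f_ij)
        cell_topo[j].face_ids.append(f_ji)
        fid += 2

    # candidate junctions: triplets mutually adjacent in the RAG
    triplets: set[tuple[int, int, int]] = set()
    for c in graph.nodes:
        for a, b in combinations(sorted(graph.neighbors(c)), 2):
            if graph.has_edge(a, b):
                triplets.add(tuple(sorted((c, a, b))))  # type: ignore[arg-type]

    edges: dict[int, EdgeRecord] = {}
    eid = 0
    for trip in sorted(triplets):
        i, j, k = trip
        pixels = find_edge_pixels(masks[i], masks[j], masks[k])
        if len(pixels) == 0:
            continue
        incident = sum(
            (pair_to_faces[pair] for pair in ((i, j), (i, k), (j, k))), ()
        )
        edges[eid] = EdgeRecord(
            edge_id=eid,
            cells=trip,
            pixels=pixels,
            z_min=int(pixels[:, 0].min()),
            z_max=int(pixels[:, 0].max()),
            face_ids=incident,
        )
        for c in trip:
            cell_topo[c].edge_ids.append(eid)
        eid += 1

    return TissueTopology(
        graph=graph, cells=cell_topo, faces=faces, edges=edges, masks=masks
    )


def detect_scutoid(
    cell: CellTopology, min_plane_voxels: int = MIN_PLANE_VOXELS
) -> tuple[bool, list[int]]:
    """Flag a cell whose in-plane neighbour set changes along depth.

    A prism keeps the same neighbours on every plane from apical to basal;
    a scutoid exchanges neighbours part-way.  Planes where the cell has
    fewer than ``min_plane_voxels`` voxels are ignored (cap artefacts).
    Returns ``(is_scutoid, exchange_planes)`` where each exchange plane is
    the z index whose neighbour set differs from the occupied plane below.

    Sensitivity note: a neighbour that simply ends mid-depth (a shorter
    cell) also changes the set and is flagged — the detector reports any
    apico-basal neighbourhood change, not only true T1-like exchanges.
    """
    planes = sorted(
        z for z, n in cell.plane_voxels.items() if n >= min_plane_voxels
    )
    if len(planes) < 2:
        raise ValueError(
            f"cell {cell.cell_id}: scutoid detection needs >= 2 usable planes"
        )
    exchange: list[int] = []
    for prev, cur in zip(planes[:-1], planes[1:]):
        if cell.plane_neighbours[cur] != cell.plane_neighbours[prev]:
            exchange.append(cur)
    return bool(exchange), exchange
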