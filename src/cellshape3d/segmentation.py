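"""Labelled-volume handling: loading, isotropic resampling, per-cell
decomposition with a compressed on-disk store, mesh export and outlier
filtering.

A *labelled volume* is a 3D integer raster indexed ``(z, y, x)`` where each
voxel value identifies the cell it belongs to and 0 is background.  All
downstream topology and morphometrics operate on this single source of
truth, usually after resampling to isotropic voxels so that distances are
comparable along every axis.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "LabeledVolume",
    "CellMask",
    "FilterRule",
    "load_labeled_volume",
    "make_isotropic",
    "decompose_cells",
    "load_cell_mask",
    "reconstruct_labels",
    "export_mesh",
    "filter_outliers",
]

_ISO_RTOL = 1e-9


@dataclasses.dataclass
class LabeledVolume:
    """A 3D labelled image plus its physical voxel spacing.

    Parameters
    ----------
    labels
        Integer array indexed ``(z, y, x)``; 0 is background, positive
        values are cell IDs.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"labelled volume must be 3D (z, y, x); got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(
                f"labels must have an integer dtype; got {self.labels.dtype}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.voxel_size
        return math.isclose(dz, dy, rel_tol=_ISO_RTOL) and math.isclose(
            dy, dx, rel_tol=_ISO_RTOL
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_ids(self) -> np.ndarray:
        """Sorted array of the nonzero labels present."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.labels, photometric="minisblack")


@dataclasses.dataclass
class CellMask:
    """One cell's binary subvolume cropped from the parent labelled volume.

    ``offset`` locates ``mask[0, 0, 0]`` in parent-volume voxel coordinates;
    components may be -1 when the 1-voxel background margin extends past the
    parent array edge.
    """

    cell_id: int
    mask: np.ndarray
    offset: tuple[int, int, int]
    padded: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"cell {self.cell_id}: mask has no foreground voxel")
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def coords(self) -> np.ndarray:
        """(N, 3) integer voxel coordinates of the cell in the parent volume."""
        return np.argwhere(self.mask) + np.asarray(self.offset)


@dataclasses.dataclass(frozen=True)
class FilterRule:
    """Closed-interval bound on one metric column; rows outside are outliers."""

    metric_name: str
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.lower_bound is None and self.upper_bound is None:
            raise ValueError(f"rule on {self.metric_name!r}: at least one bound required")
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and self.lower_bound > self.upper_bound
        ):
            raise ValueError(
                f"rule on {self.metric_name!r}: lower bound exceeds upper bound"
            )


def load_labeled_volume(
    path: str | Path, voxel_size: Sequence[float]
) -> LabeledVolume:
    """Read a single-channel integer TIFF stack as a labelled volume.

    Raises on 2D input: single optical sections carry no apico-basal
    information and are out of scope for 3D shape analysis.
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise ValueError("input is a single 2D plane; a 3D stack is required")
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D single-channel stack, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"label stacks must be integer-typed, got {arr.dtype}; "
            "intensity images are not labelled segmentations"
        )
    return LabeledVolume(labels=arr, voxel_size=tuple(voxel_size))


def make_isotropic(vol: LabeledVolume) -> LabeledVolume:
    """Resample to cubic voxels with edge min(dz, dy, dx).

    Nearest-neighbour interpolation only: any averaging scheme would invent
    label values at cell interfaces.  Upsampling to the finest existing
    spacing preserves in-plane resolution.  Already-isotropic volumes are
    returned unchanged (same array object).
    """
    if vol.is_isotropic:
        return vol
    target = min(vol.voxel_size)
    factors = tuple(v / target for v in vol.voxel_size)
    resampled = ndimage.zoom(vol.labels, factors, order=0, mode="nearest", prefilter=False)
    return LabeledVolume(labels=resampled, voxel_size=(target, target, target))


def _crop_with_margin(labels: np.ndarray, cell_id: int, slc: tuple[slice, ...]) -> CellMask:
    # Pad one background voxel on every side so a 1-voxel dilation never
    # leaves the array; offsets may go to -1 at the volume border.
    sub = labels[slc] == cell_id
    mask = np.pad(sub, 1)
    offset = tuple(int(s.start) - 1 for s in slc)
    return CellMask(cell_id=int(cell_id), mask=mask, offset=offset, padded=True)


def decompose_cells(
    vol: LabeledVolume, store_dir: str | Path | None = None
) -> list[CellMask]:
    """Split a labelled volume into per-cell binary masks.

    Each mask is the cell's bounding box plus a one-voxel background
    margin.  When ``store_dir`` is given, every mask is written there as a
    compressed NPZ named ``cell_<id>.npz`` holding mask, offset, voxel size
    and id — the round trip through :func:`load_cell_mask` is lossless.
    """
    objects = ndimage.find_objects(vol.labels)
    cells: list[CellMask] = []
    for idx, slc in enumerate(objects):
        if slc is None:
            continue
        cells.append(_crop_with_margin(vol.labels, idx + 1, slc))
    if store_dir is not None:
        store = Path(store_dir)
        store.mkdir(parents=True, exist_ok=True)
        for cell in cells:
            np.savez_compressed(
                store / f"cell_{cell.cell_id:06d}.npz",
                cell_id=np.int64(cell.cell_id),
                mask=cell.mask,
                offset=np.asarray(cell.offset, dtype=np.int64),
                voxel_size=np.asarray(vol.voxel_size, dtype=float),
                padded=np.bool_(cell.padded),
            )
    return cells


def load_cell_mask(path: str | Path) -> CellMask:
    """Read one cell back from the compressed per-cell store."""
    with np.load(path) as data:
        return CellMask(
            cell_id=int(data["cell_id"]),
            mask=data["mask"].astype(bool),
            offset=tuple(int(v) for v in data["offset"]),
            padded=bool(data["padded"]),
        )


def reconstruct_labels(
    cells: Iterable[CellMask], shape: tuple[int, int, int]
) -> np.ndarray:
    """Reassemble a label array from per-cell masks placed at their offsets."""
    out = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        coords = cell.coords()
        keep = np.all((coords >= 0) & (coords < np.asarray(shape)), axis=1)
        coords = coords[keep]
        out[coords[:, 0], coords[:, 1], coords[:, 2]] = cell.cell_id
    return out


def export_mesh(
    cell: CellMask,
    path: str | Path,
    voxel_size: Sequence[float] | float = 1.0,
    fmt: str | None = None,
):
    """Write a closed triangulated surface of the cell as OBJ or PLY (ASCII).

    The surface is extracted by marching cubes at the 0.5 iso-level of the
    padded binary mask and scaled to micrometres.  Returns the
    :class:`trimesh.Trimesh` that was written.
    """
    import trimesh
    from skimage import measure

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in {"obj", "ply"}:
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
    if np.isscalar(voxel_size):
        spacing = (float(voxel_size),) * 3
    else:
        spacing = tuple(float(v) for v in voxel_size)  # type: ignore[arg-type]
    mask = cell.mask if cell.padded else np.pad(cell.mask, 1)
    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.uint8), level=0.5, spacing=spacing
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # wind faces outward so the signed volume is positive
        mesh.invert()
    if fmt == "ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    return mesh


def filter_outliers(
    table: pd.DataFrame, rules: Sequence[FilterRule]
) -> tuple[pd.DataFrame, list[int]]:
    """Drop rows violating any bound; return (kept table, removed cell ids).

    Intended for post-hoc pruning of metric tables, e.g. removing
    implausibly large "cells" that are two merged segments.  Idempotent and
    order-independent across rules.  ``table`` must be indexed by cell id or
    carry a ``cell_id`` column.
    """
    for rule in rules:
        if rule.metric_name not in table.columns:
            raise KeyError(f"metric {rule.metric_name!r} not present in table")
    keep = pd.Series(True, index=table.index)
    for rule in rules:
        col = table[rule.metric_name]
        if rule.lower_bound is not None:
            keep &= col >= rule.lower_bound
        if rule.upper_bound is not None:
            keep &= col <= rule.upper_bound
    removed = table.index[~keep]
    if "cell_id" in table.columns:
        removed_ids = [int(i) for i in table.loc[removed, "cell_id"]]
    else:
        removed_ids = [int(i) for i in removed]
    return table[keep], removed_ids
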