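"""Synthetic ground-truth tissues from seeded Voronoi pavements.

A 2D Voronoi pavement (each pixel labelled by its nearest seed) replicated
across z gives a columnar *prism* tissue whose adjacency, centroids and
areas are known exactly from the pavement — the entire test-fixture
surface of the package.  Variants exercise specific detectors:

* ``scutoid`` — two pavements from the same seeds with one adjacent pair
  perturbed until a wall flips (a T1-like exchange); planes below the
  exchange plane use the first pavement, planes above the second, so the
  cells whose pavement adjacency differs are ground-truth scutoids.
* ``tilted`` — the pavement sheared along x by tan(tilt) pixels per plane.
* ``twisted`` — a disk-masked pavement rotated by (rate × z) degrees per
  plane about the patch centre, nearest-neighbour resampled.

All generators are deterministic given (rng seed, spec) and use a 1 µm
isotropic voxel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import LabeledVolume

__all__ = [
    "SyntheticTissueSpec",
    "voronoi_pavement",
    "pavement_adjacency",
    "generate_prism_tissue",
    "generate_scutoid_tissue",
    "generate_tilted_or_twisted",
    "variant_resize_and_crop",
    "save_tissue",
]

#: minimum seed separation, as a fraction of the expected seed spacing
#: sqrt(domain area / n_seeds); prevents sliver cells
MIN_SEED_SPACING_FRACTION = 0.3


@dataclasses.dataclass
class SyntheticTissueSpec:
    shape: tuple[int, int, int]  # (z, y, x)
    n_seeds: int
    rng_seed: int
    pattern: str = "prism"
    exchange_plane: int | None = None
    tilt_deg: float | None = None
    twist_rate_deg_per_plane: float | None = None
    border_crop: bool = False

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        if self.n_seeds < 2:
            raise ValueError("at least 2 seeds required")
        if self.pattern not in {"prism", "scutoid", "tilted", "twisted"}:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "scutoid":
            if self.exchange_plane is None:
                self.exchange_plane = self.shape[0] // 2
            if not 0 < self.exchange_plane < self.shape[0]:
                raise ValueError(
                    f"exchange plane {self.exchange_plane} outside the open z-range"
                )
        if self.pattern == "tilted":
            if self.tilt_deg is None or not 0 <= self.tilt_deg < 90:
                raise ValueError("tilted pattern needs 0 <= tilt_deg < 90")
        if self.pattern == "twisted" and self.twist_rate_deg_per_plane is None:
            raise ValueError("twisted pattern needs twist_rate_deg_per_plane")


def _draw_seeds(rng: np.random.Generator, n: int, ny: int, nx: int) -> np.ndarray:
    spacing = math.sqrt(ny * nx / n)
    min_dist = MIN_SEED_SPACING_FRACTION * spacing
    seeds: list[np.ndarray] = []
    for _ in range(200 * n):
        cand = rng.uniform([0, 0], [ny, nx])
        if all(np.linalg.norm(cand - s) >= min_dist for s in seeds):
            seeds.append(cand)
            if len(seeds) == n:
                return np.array(seeds)
    raise RuntimeError(f"could not place {n} seeds with spacing {min_dist:.2f}")


def voronoi_pavement(seeds: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Label each pixel 1..n by nearest seed (pixel centres at integers)."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    _, idx = cKDTree(seeds).query(pts)
    return (idx.reshape(ny, nx) + 1).astype(np.int32)


def pavement_adjacency(pavement: np.ndarray) -> set[tuple[int, int]]:
    """Exhaustive 4-connected differing-label pixel-pair scan of a pavement."""
    pairs: set[tuple[int, int]] = set()
    for ax in range(2):
        a = np.moveaxis(pavement, ax, 0)[:-1]
        b = np.moveaxis(pavement, ax, 0)[1:]
        touching = (a != b) & (a > 0) & (b > 0)
        if touching.any():
            stacked = np.stack([a[touching], b[touching]])
            lo, hi = stacked.min(axis=0), stacked.max(axis=0)
            pairs.update(
                (int(i), int(j)) for i, j in np.unique(np.stack([lo, hi], 1), axis=0)
            )
    return pairs


def _neighbour_sets(pairs: set[tuple[int, int]], labels) -> dict[int, frozenset[int]]:
    out: dict[int, set[int]] = {int(l): set() for l in labels}
    for i, j in pairs:
        out[i].add(j)
        out[j].add(i)
    return {k: frozenset(v) for k, v in out.items()}


def generate_prism_tissue(
    spec: SyntheticTissueSpec,
) -> tuple[LabeledVolume, dict[str, Any]]:
    """Columnar tissue: one Voronoi pavement replicated across all planes."""
    nz, ny, nx = spec.shape
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _draw_seeds(rng, spec.n_seeds, ny, nx)
    pav = voronoi_pavement(seeds, ny, nx)
    vol = LabeledVolume(
        labels=np.broadcast_to(pav, (nz, ny, nx)).copy(), voxel_size=(1.0, 1.0, 1.0)
    )
    ids, counts = np.unique(pav, return_counts=True)
    centroids = {
        int(l): tuple(np.argwhere(pav == l).mean(axis=0)) for l in ids
    }
    truth: dict[str, Any] = {
        "pattern": "prism",
        "adjacency": sorted(pavement_adjacency(pav)),
        "areas": {int(l): int(c) for l, c in zip(ids, counts)},
        "centroids": centroids,
        "seeds": seeds.tolist(),
    }
    return vol, truth


def generate_scutoid_tissue(
    spec: SyntheticTissueSpec, max_retries: int = 50
) -> tuple[LabeledVolume, dict[str, Any]]:
    """Tissue with one T1-like neighbour exchange at ``exchange_plane``.

    An adjacent seed pair is moved apart along its connecting line until
    the pavement adjacency changes (their shared wall collapses and the
    two flanking cells gain one).  Every cell's region in the two
    pavements must overlap, so cells stay 6-connected columns in 3D.
    """
    nz, ny, nx = spec.shape
    e = spec.exchange_plane
    assert e is not None
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _draw_seeds(rng, spec.n_seeds, ny, nx)
    pav_a = voronoi_pavement(seeds, ny, nx)
    adj_a = pavement_adjacency(pav_a)
    candidates = sorted(adj_a)
    rng.shuffle(candidates)
    labels = np.unique(pav_a)
    sets_a = _neighbour_sets(adj_a, labels)
    tried = 0
    for i, j in candidates:
        si, sj = seeds[i - 1], seeds[j - 1]
        direction = sj - si
        dist = np.linalg.norm(direction)
        if dist < 1e-9:
            continue
        direction = direction / dist
        for frac in (0.2, 0.35, 0.5, 0.75, 1.0):
            tried += 1
            if tried > max_retries:
                raise RuntimeError("could not construct a neighbour exchange")
            moved = seeds.copy()
            moved[i - 1] = si - direction * frac * dist / 2
            moved[j - 1] = sj + direction * frac * dist / 2
            pav_b = voronoi_pavement(moved, ny, nx)
            if not np.array_equal(np.unique(pav_b), labels):
                continue  # a cell vanished
            adj_b = pavement_adjacency(pav_b)
            if adj_b == adj_a:
                continue
            overlap_ok = all(
                np.any((pav_a == l) & (pav_b == l)) for l in labels
            )
            if not overlap_ok:
                continue
            sets_b = _neighbour_sets(adj_b, labels)
            exchanging = sorted(
                int(l) for l in labels if sets_a[int(l)] != sets_b[int(l)]
            )
            vol_arr = np.empty((nz, ny, nx), dtype=np.int32)
            vol_arr[:e] = pav_a
            vol_arr[e:] = pav_b
            truth: dict[str, Any] = {
                "pattern": "scutoid",
                "exchange_plane": int(e),
                "exchanging_cells": exchanging,
                "adjacency_basal": sorted(adj_a),
                "adjacency_apical": sorted(adj_b),
                "perturbed_pair": [int(i), int(j)],
            }
            return LabeledVolume(vol_arr, (1.0, 1.0, 1.0)), truth
    raise RuntimeError("could not construct a neighbour exchange")


def generate_tilted_or_twisted(
    spec: SyntheticTissueSpec,
) -> tuple[LabeledVolume, dict[str, Any]]:
    """Sheared (tilted) or per-plane-rotated (twisted) columnar tissue."""
    nz, ny, nx = spec.shape
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _draw_seeds(rng, spec.n_seeds, ny, nx)
    pav = voronoi_pavement(seeds, ny, nx)
    if spec.pattern == "tilted":
        tilt = float(spec.tilt_deg)  # type: ignore[arg-type]
        shear = math.tan(math.radians(tilt))
        max_shift = int(round(shear * (nz - 1)))
        arr = np.zeros((nz, ny, nx + max_shift), dtype=np.int32)
        shifts = [int(round(shear * z)) for z in range(nz)]
        for z, s in enumerate(shifts):
            arr[z, :, s : s + nx] = pav
        truth: dict[str, Any] = {
            "pattern": "tilted",
            "tilt_deg": tilt,
            "shifts": shifts,
            "adjacency": sorted(pavement_adjacency(pav)),
        }
        return LabeledVolume(arr, (1.0, 1.0, 1.0)), truth
    if spec.pattern == "twisted":
        rate = float(spec.twist_rate_deg_per_plane)  # type: ignore[arg-type]
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        radius = min(ny, nx) / 2.0 - 2.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        arr = np.zeros((nz, ny, nx), dtype=np.int32)
        for z in range(nz):
            # sample source = target rotated by −θ, so the pattern turns by
            # +θ right-handed about +z (counter-clockwise in atan2(dy, dx))
            theta = math.radians(rate * z)
            c, s = math.cos(theta), math.sin(theta)
            sy = cy + (yy - cy) * c - (xx - cx) * s
            sx = cx + (yy - cy) * s + (xx - cx) * c
            iy = np.clip(np.round(sy).astype(int), 0, ny - 1)
            ix = np.clip(np.round(sx).astype(int), 0, nx - 1)
            plane = pav[iy, ix]
            plane[~disk] = 0
            arr[z] = plane
        truth = {
            "pattern": "twisted",
            "twist_rate_deg_per_plane": rate,
            "rotation_deg_by_plane": [rate * z for z in range(nz)],
            "centre_yx": [cy, cx],
            "radius": radius,
        }
        return LabeledVolume(arr, (1.0, 1.0, 1.0)), truth
    raise ValueError(f"pattern {spec.pattern!r} is not tilted/twisted")


def variant_resize_and_crop(
    vol: LabeledVolume,
    target_shape: tuple[int, int, int] | None = None,
    border_crop: bool = False,
) -> LabeledVolume:
    """Nearest-neighbour resize and/or removal of xy-border cells.

    Border cropping sets every label touching the xy boundary to
    background, emulating the construction of interior-only datasets with
    unchanged average cell size.
    """
    labels = vol.labels
    if target_shape is not None:
        if any(t < 8 for t in target_shape):
            raise ValueError(f"target shape too small: {target_shape}")
        idx = [
            np.floor((np.arange(t) + 0.5) * labels.shape[ax] / t).astype(int)
            for ax, t in enumerate(target_shape)
        ]
        labels = labels[np.ix_(idx[0], idx[1], idx[2])]
    if border_crop:
        labels = labels.copy()
        border_ids = np.unique(
            np.concatenate(
                [
                    labels[:, 0, :].ravel(),
                    labels[:, -1, :].ravel(),
                    labels[:, :, 0].ravel(),
                    labels[:, :, -1].ravel(),
                ]
            )
        )
        labels[np.isin(labels, border_ids[border_ids > 0])] = 0
    return LabeledVolume(labels, vol.voxel_size)


def save_tissue(
    vol: LabeledVolume, truth: dict[str, Any], out_dir: str | Path, name: str
) -> tuple[Path, Path]:
    """Write the labelled TIFF stack plus its ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{name}.tif"
    js = out / f"{name}.json"
    vol.save(tif)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    js.write_text(json.dumps(truth, indent=1, default=_default))
    return tif, js
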