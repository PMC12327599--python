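"""Pipeline orchestration: run the decomposition and metric stages on a
labelled volume and write the linked CSV tables, graph exports and a run
manifest.

Stages form a small dependency graph — every metric stage needs the
topology tables, and twist additionally needs cell centrelines and edge
geometry.  Per-cell work is distributed over joblib workers; rows are
keyed by id and sorted before writing, so output tables are byte-identical
whatever the worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .cell_metrics import compute_cell_metrics, plane_centroid_centreline
from .face_edge import (
    compute_twist,
    edge_geometry,
    face_area_perimeter,
    face_per_plane,
    fit_face_plane,
)
from .plane_metrics import cell_plane_metrics, neighbour_count_2d_vs_3d
from .segmentation import (
    FilterRule,
    LabeledVolume,
    decompose_cells,
    filter_outliers,
    load_labeled_volume,
    make_isotropic,
)
from .topology import TissueTopology, build_topology_tables, detect_scutoid

log = logging.getLogger("cellshape3d")

ALL_STAGES = ("topology", "cell", "plane", "face_edge", "twist")
_STAGE_DEPS = {
    "topology": set(),
    "cell": {"topology"},
    "plane": {"topology"},
    "face_edge": {"topology"},
    "twist": {"topology", "cell", "face_edge"},
}


@dataclasses.dataclass
class PipelineConfig:
    input_path: str | Path | None  # None when a volume is passed directly
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    output_dir: str | Path = "cellshape3d_out"
    stages: tuple[str, ...] = ALL_STAGES
    workers: int = 1
    filter_rules: Sequence[FilterRule] = ()
    export_meshes: bool = False
    store_cells: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")
        stages = set(self.stages)
        unknown = stages - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for st in stages:
            missing = _STAGE_DEPS[st] - stages
            if missing:
                raise ValueError(
                    f"stage {st!r} requires {sorted(missing)}; "
                    "stages must form a dependency-closed set"
                )


def _graph_outputs(topo: TissueTopology, out: Path) -> list[Path]:
    edge_list = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in topo.graph.edges),
        columns=["cell_i", "cell_j"],
    )
    p1 = out / "graph_edges.csv"
    edge_list.to_csv(p1, index=False)
    p2 = out / "graph.graphml"
    nx.write_graphml(topo.graph, p2)
    return [p1, p2]


def _cell_stage(topo: TissueTopology, voxel_size, workers: int) -> pd.DataFrame:
    cells = [topo.masks[c] for c in sorted(topo.masks)]
    metrics = Parallel(n_jobs=workers)(
        delayed(compute_cell_metrics)(c, voxel_size) for c in cells
    )
    rows = []
    for m in metrics:
        row = dataclasses.asdict(m)
        ct = topo.cells[m.cell_id]
        try:
            is_scutoid, exchanges = detect_scutoid(ct)
            row["is_scutoid"] = is_scutoid
            row["n_exchange_planes"] = len(exchanges)
        except ValueError:
            row["is_scutoid"] = None
            row["n_exchange_planes"] = None
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def _plane_stage(topo: TissueTopology, voxel_size, workers: int) -> pd.DataFrame:
    cells = [topo.masks[c] for c in sorted(topo.masks)]
    per_cell = Parallel(n_jobs=workers)(
        delayed(cell_plane_metrics)(c, voxel_size) for c in cells
    )
    rows = []
    for cell_rows in per_cell:
        for pm in cell_rows:
            row = dataclasses.asdict(pm)
            ct = topo.cells[pm.cell_id]
            row["n_neighbours_plane"] = len(ct.plane_neighbours.get(pm.z, ()))
            rows.append(row)
    return (
        pd.DataFrame(rows).sort_values(["cell_id", "z"]).reset_index(drop=True)
    )


def _face_edge_stage(topo: TissueTopology, voxel_size):
    face_rows, face_plane_rows, edge_rows = [], [], []
    fit_cache: dict[int, tuple] = {}
    for fid in sorted(topo.faces):
        fr = topo.faces[fid]
        key = min(fid, fr.mirror_face_id)
        if key not in fit_cache:
            try:
                fit = fit_face_plane(fr, voxel_size)
                area, perim = face_area_perimeter(fit, voxel_size)
                fit_cache[key] = (fit, area, perim)
            except ValueError as err:
                log.warning("degenerate face %d: %s", fid, err)
                fit_cache[key] = (None, np.nan, np.nan)
        fit, area, perim = fit_cache[key]
        row = {
            "face_id": fid,
            "cell_id": fr.cell_id,
            "opposite_cell_id": fr.opposite_cell_id,
            "mirror_face_id": fr.mirror_face_id,
            "n_pixels": len(fr.pixels),
            "area": area,
            "perimeter": perim,
        }
        if fit is not None:
            row["flatness"] = fit.flatness
            row["normal_z"], row["normal_y"], row["normal_x"] = fit.normal
        else:
            row["flatness"] = np.nan
            row["normal_z"] = row["normal_y"] = row["normal_x"] = np.nan
        face_rows.append(row)
        if fid < fr.mirror_face_id:  # per-plane rows once per contact
            for z, length, angle in face_per_plane(fr, voxel_size):
                face_plane_rows.append(
                    {"face_id": fid, "z": z, "length": length, "angle": angle}
                )
    geoms = {}
    for eid in sorted(topo.edges):
        eg = edge_geometry(topo.edges[eid], voxel_size)
        geoms[eid] = eg
        er = topo.edges[eid]
        edge_rows.append(
            {
                "edge_id": eid,
                "cell_1": er.cells[0],
                "cell_2": er.cells[1],
                "cell_3": er.cells[2],
                "z_min": er.z_min,
                "z_max": er.z_max,
                "n_pixels": len(er.pixels),
                "real_length": eg.real_length,
                "straight_length": eg.straight_length,
                "tortuosity": eg.tortuosity,
            }
        )
    face_df = pd.DataFrame(face_rows)
    face_plane_df = pd.DataFrame(
        face_plane_rows, columns=["face_id", "z", "length", "angle"]
    )
    edge_df = pd.DataFrame(
        edge_rows,
        columns=[
            "edge_id", "cell_1", "cell_2", "cell_3", "z_min", "z_max",
            "n_pixels", "real_length", "straight_length", "tortuosity",
        ],
    )
    return face_df, face_plane_df, edge_df, geoms


def _twist_stage(topo: TissueTopology, voxel_size, geoms) -> pd.DataFrame:
    rows = []
    for cid in sorted(topo.cells):
        ct = topo.cells[cid]
        row = {"cell_id": cid, "total_twist": np.nan, "twist_rate": np.nan,
               "n_edges_used": 0, "status": ""}
        try:
            cl = plane_centroid_centreline(topo.masks[cid], voxel_size)
        except ValueError:
            row["status"] = "single_plane_cell"
            rows.append(row)
            continue
        edges = [geoms[e] for e in ct.edge_ids if e in geoms]
        profile = compute_twist(ct, cl, edges, voxel_size)
        if profile is None:
            row["status"] = "fewer_than_two_usable_edges"
        else:
            row.update(
                total_twist=profile.total_twist,
                twist_rate=profile.twist_rate,
                n_edges_used=profile.n_edges,
                status="ok",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig, volume: LabeledVolume | None = None
) -> dict[str, Path]:
    """Execute the configured stages and write all output tables.

    Returns a mapping from output name to written path.  ``volume`` may be
    passed directly (synthetic mode); otherwise ``config.input_path`` is
    read as a labelled TIFF stack.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        if volume is None:
            if config.input_path is None:
                raise ValueError("either an input path or a volume is required")
            volume = load_labeled_volume(config.input_path, config.voxel_size)
        log.info("input volume %s, voxel %s", volume.shape, volume.voxel_size)
        volume = make_isotropic(volume)
        vs = volume.voxel_size

        store_dir = out / "cells" if config.store_cells else None
        cells = decompose_cells(volume, store_dir)
        log.info("decomposed %d cells", len(cells))

        log.info("stage topology: start")
        topo = build_topology_tables(volume, cells)
        log.info("stage topology: %d faces, %d edges", len(topo.faces), len(topo.edges))
        cell_df = topo.cell_table()
        face_df = topo.face_table()
        edge_df = topo.edge_table()

        n2d3d = neighbour_count_2d_vs_3d(topo)
        cell_df["n_neighbours_2d"] = [n2d3d[c][0] for c in cell_df["cell_id"]]
        cell_df["n_neighbours_3d"] = [n2d3d[c][1] for c in cell_df["cell_id"]]

        if "cell" in config.stages:
            log.info("stage cell: start")
            metrics_df = _cell_stage(topo, vs, config.workers)
            cell_df = cell_df.merge(metrics_df, on="cell_id", how="left")

        if "plane" in config.stages:
            log.info("stage plane: start")
            plane_df = _plane_stage(topo, vs, config.workers)
            p = out / "plane_df.csv"
            plane_df.to_csv(p, index=False)
            outputs["plane_df"] = p

        geoms = None
        if "face_edge" in config.stages:
            log.info("stage face_edge: start")
            face_df, face_plane_df, edge_df, geoms = _face_edge_stage(topo, vs)
            p = out / "face_plane_df.csv"
            face_plane_df.to_csv(p, index=False)
            outputs["face_plane_df"] = p

        if "twist" in config.stages:
            log.info("stage twist: start")
            twist_df = _twist_stage(topo, vs, geoms or {})
            p = out / "twist_df.csv"
            twist_df.to_csv(p, index=False)
            outputs["twist_df"] = p

        removed_ids: list[int] = []
        if config.filter_rules:
            cell_df, removed_ids = filter_outliers(
                cell_df, list(config.filter_rules)
            )
            log.info("outlier filter removed cells %s", removed_ids)

        cell_df = cell_df.sort_values("cell_id").reset_index(drop=True)
        for name, df in (("cell_df", cell_df), ("face_df", face_df),
                         ("edge_df", edge_df)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            outputs[name] = p
        for p in _graph_outputs(topo, out):
            outputs[p.stem] = p

        if config.export_meshes:
            from .segmentation import export_mesh

            mesh_dir = out / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            for cell in cells:
                export_mesh(cell, mesh_dir / f"cell_{cell.cell_id:06d}.obj", vs)
            outputs["meshes"] = mesh_dir

        manifest = {
            "package": "cellshape3d",
            "version": __version__,
            "config": {
                "input_path": str(config.input_path) if config.input_path else None,
                "voxel_size": list(config.voxel_size),
                "stages": list(config.stages),
                "workers": config.workers,
                "rng_seed": config.rng_seed,
                "filter_rules": [dataclasses.asdict(r) for r in config.filter_rules],
            },
            "n_cells": len(cells),
            "removed_cell_ids": removed_ids,
        }
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, indent=1))
        outputs["manifest"] = p
        log.info("pipeline complete: %d outputs", len(outputs))
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()
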