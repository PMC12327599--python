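import numpy as np
import pytest

from cellshape3d import (
    CellMask,
    LabeledVolume,
    build_rag,
    build_topology_tables,
    decompose_cells,
    detect_scutoid,
    dilate_mask,
    find_edge_pixels,
    find_face_pixels,
    find_neighbours,
    voxel_pair_adjacency,
)
from cellshape3d.synthetic import SyntheticTissueSpec, generate_prism_tissue

from conftest import cube_mask


def single_voxel_mask():
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    return CellMask(cell_id=1, mask=mask, offset=(0, 0, 0), padded=True)


class TestDilateMask:
    def test_single_voxel_becomes_six_connected_plus(self):
        dil = dilate_mask(single_voxel_mask())
        assert dil.mask.sum() == 7
        # no corner/edge voxels: 6-connectivity only
        assert not dil.mask[0, 0, 0] and not dil.mask[0, 0, 1]

    def test_cube_gains_one_face_slab_per_side(self):
        dil = dilate_mask(cube_mask(10))
        assert dil.mask.sum() == 1000 + 600

    def test_dilation_is_extensive(self, prism_topology):
        for cid, cell in list(prism_topology.masks.items())[:5]:
            dil = dilate_mask(cell)
            assert np.all(dil.mask[cell.mask])


class TestFindNeighbours:
    def test_isolated_cell_has_no_neighbours(self):
        arr = np.zeros((6, 6, 6), dtype=np.int32)
        arr[2:4, 2:4, 2:4] = 1
        vol = LabeledVolume(arr, (1, 1, 1))
        (cell,) = decompose_cells(vol)
        assert find_neighbours(vol, cell) == set()

    def test_two_abutting_cuboids_are_mutual(self, two_cuboids):
        c1, c2 = decompose_cells(two_cuboids)
        assert find_neighbours(two_cuboids, c1) == {2}
        assert find_neighbours(two_cuboids, c2) == {1}

    def test_absent_cell_raises(self, two_cuboids):
        ghost = single_voxel_mask()
        ghost.cell_id = 99
        with pytest.raises(ValueError, match="99"):
            find_neighbours(two_cuboids, ghost)

    def test_brick_wall_matches_exhaustive_scan(self):
        # 3 cells: one spanning brick on top of two half bricks
        arr = np.zeros((4, 8, 12), dtype=np.int32)
        arr[:, :4, :] = 1
        arr[:, 4:, :6] = 2
        arr[:, 4:, 6:] = 3
        vol = LabeledVolume(arr, (1, 1, 1))
        rag = build_rag(vol)
        assert set(tuple(sorted(e)) for e in rag.edges) == voxel_pair_adjacency(arr)

    def test_diagonal_only_contact_is_not_adjacency(self):
        arr = np.zeros((3, 4, 4), dtype=np.int32)
        arr[:, :2, :2] = 1
        arr[:, 2:, 2:] = 2  # corner contact only
        vol = LabeledVolume(arr, (1, 1, 1))
        rag = build_rag(vol)
        assert rag.number_of_edges() == 0


class TestBuildRag:
    def test_single_cell_volume(self):
        arr = np.zeros((6, 6, 6), dtype=np.int32)
        arr[1:5, 1:5, 1:5] = 1
        rag = build_rag(LabeledVolume(arr, (1, 1, 1)))
        assert rag.number_of_nodes() == 1 and rag.number_of_edges() == 0

    def test_grid_of_cuboids_forms_grid_adjacency(self):
        arr = np.zeros((4, 10, 10), dtype=np.int32)
        arr[:, :5, :5] = 1
        arr[:, :5, 5:] = 2
        arr[:, 5:, :5] = 3
        arr[:, 5:, 5:] = 4
        rag = build_rag(LabeledVolume(arr, (1, 1, 1)))
        assert set(tuple(sorted(e)) for e in rag.edges) == {
            (1, 2), (1, 3), (2, 4), (3, 4)
        }

    def test_voronoi_tissue_matches_oracle_and_ground_truth(self, prism_tissue):
        vol, truth = prism_tissue
        rag = set(tuple(sorted(e)) for e in build_rag(vol).edges)
        assert rag == voxel_pair_adjacency(vol.labels)
        assert rag == set(map(tuple, truth["adjacency"]))


class TestFacePixels:
    def test_shared_wall_pixels_span_wall(self, two_cuboids):
        c1, c2 = decompose_cells(two_cuboids)
        px = find_face_pixels(c1, c2)
        assert len(px) == 2 * 8 * 10  # one shell layer per cell
        assert set(px[:, 2]) == {9, 10}

    def test_symmetric_and_empty_for_non_adjacent(self, three_strips):
        c1, c2, c3 = decompose_cells(three_strips)
        a = find_face_pixels(c1, c2)
        b = find_face_pixels(c2, c1)
        assert np.array_equal(a, b)
        assert len(find_face_pixels(c1, c3)) == 0

    def test_same_cell_rejected(self, two_cuboids):
        c1, _ = decompose_cells(two_cuboids)
        with pytest.raises(ValueError):
            find_face_pixels(c1, c1)


class TestEdgePixels:
    def test_three_prisms_meet_along_full_vertical_line(self, triple_junction):
        c1, c2, c3 = decompose_cells(triple_junction)
        px = find_edge_pixels(c1, c2, c3)
        assert len(px) > 0
        assert set(px[:, 0]) == set(range(10))  # spans all z planes

    def test_non_adjacent_triplet_is_empty(self, three_strips):
        c1, c2, c3 = decompose_cells(three_strips)
        # 1 and 3 never touch, so no common junction exists
        assert len(find_edge_pixels(c1, c2, c3)) == 0

    def test_distinct_ids_required(self, triple_junction):
        c1, c2, _ = decompose_cells(triple_junction)
        with pytest.raises(ValueError):
            find_edge_pixels(c1, c2, c2)

    def test_scutoid_edge_has_partial_z_extent(self, scutoid_topology, scutoid_tissue):
        _, truth = scutoid_tissue
        nz_minus1 = 15
        partial = [
            e for e in scutoid_topology.edges.values()
            if e.z_min > 0 or e.z_max < nz_minus1
        ]
        assert partial, "a neighbour exchange must create partial-depth junctions"


class TestTopologyTables:
    def test_honeycomb_central_cell(self):
        # 7 hexagonally arranged seeds: central cell has 6 faces and 6 edges
        from cellshape3d.synthetic import voronoi_pavement

        centre = np.array([40.0, 40.0])
        ring = [
            centre + 26 * np.array([np.cos(a), np.sin(a)])
            for a in np.linspace(0, 2 * np.pi, 7)[:-1]
        ]
        seeds = np.vstack([centre, ring])
        pav = voronoi_pavement(seeds, 80, 80)
        vol = LabeledVolume(
            np.broadcast_to(pav, (12, 80, 80)).copy(), (1, 1, 1)
        )
        topo = build_topology_tables(vol)
        central = topo.cells[1]
        assert len(central.face_ids) == 6
        assert len(central.edge_ids) == 6
        assert not central.is_border
        assert all(topo.cells[c].is_border for c in range(2, 8))

    def test_half_face_count_and_mirror_involution(self, prism_topology):
        topo = prism_topology
        assert len(topo.faces) == 2 * topo.graph.number_of_edges()
        for f in topo.faces.values():
            mirror = topo.faces[f.mirror_face_id]
            assert mirror.mirror_face_id == f.face_id
            assert (mirror.cell_id, mirror.opposite_cell_id) == (
                f.opposite_cell_id, f.cell_id
            )
            assert np.array_equal(mirror.pixels, f.pixels)

    def test_every_edge_triplet_is_a_rag_triangle(self, prism_topology):
        g = prism_topology.graph
        for e in prism_topology.edges.values():
            i, j, k = e.cells
            assert g.has_edge(i, j) and g.has_edge(i, k) and g.has_edge(j, k)

    def test_edge_pixels_subset_of_incident_face_pixels(self, prism_topology):
        topo = prism_topology
        for e in topo.edges.values():
            edge_set = set(map(tuple, e.pixels))
            for fid in e.face_ids[::2]:  # one half-face per pair
                face_set = set(map(tuple, topo.faces[fid].pixels))
                assert edge_set <= face_set

    def test_face_list_matches_neighbour_set(self, prism_topology):
        for ct in prism_topology.cells.values():
            assert len(ct.face_ids) == len(ct.neighbours)

    def test_plane_neighbour_union_equals_neighbour_set(self, prism_topology):
        # holds for columnar tissues where every contact is lateral
        for ct in prism_topology.cells.values():
            union = frozenset().union(*ct.plane_neighbours.values())
            assert union == ct.neighbours


class TestDetectScutoid:
    def test_prisms_are_not_scutoids(self, prism_topology):
        for ct in prism_topology.cells.values():
            flagged, planes = detect_scutoid(ct)
            assert not flagged and planes == []

    def test_constructed_exchange_at_mid_depth(self):
        # left half constant cell 1; right half switches 2 -> 3 at z = 8
        arr = np.zeros((16, 10, 20), dtype=np.int32)
        arr[:, :, :10] = 1
        arr[:8, :, 10:] = 2
        arr[8:, :, 10:] = 3
        topo = build_topology_tables(LabeledVolume(arr, (1, 1, 1)))
        flagged, planes = detect_scutoid(topo.cells[1])
        assert flagged and planes == [8]

    def test_neighbour_ending_mid_depth_is_flagged(self):
        # documented sensitivity: a shorter neighbour changes the set too
        arr = np.zeros((16, 10, 20), dtype=np.int32)
        arr[:, :, :10] = 1
        arr[:8, :, 10:] = 2  # neighbour 2 stops at z = 8
        topo = build_topology_tables(LabeledVolume(arr, (1, 1, 1)))
        flagged, planes = detect_scutoid(topo.cells[1])
        assert flagged and planes == [8]

    def test_single_plane_cell_is_degenerate(self):
        arr = np.zeros((8, 8, 8), dtype=np.int32)
        arr[4, 2:6, 2:6] = 1
        topo = build_topology_tables(LabeledVolume(arr, (1, 1, 1)))
        with pytest.raises(ValueError, match="planes"):
            detect_scutoid(topo.cells[1])

    def test_generator_ground_truth_recovered(self, scutoid_topology, scutoid_tissue):
        _, truth = scutoid_tissue
        flagged = {
            cid for cid, ct in scutoid_topology.cells.items()
            if detect_scutoid(ct)[0]
        }
        assert flagged == set(truth["exchanging_cells"])
        for cid in flagged:
            _, planes = detect_scutoid(scutoid_topology.cells[cid])
            assert planes == [truth["exchange_plane"]]


def test_rag_oracle_equivalence_on_random_small_tissues():
    for seed in range(5):
        spec = SyntheticTissueSpec(shape=(12, 60, 60), n_seeds=8, rng_seed=seed)
        vol, _ = generate_prism_tissue(spec)
        rag = set(tuple(sorted(e)) for e in build_rag(vol).edges)
        assert rag == voxel_pair_adjacency(vol.labels)
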