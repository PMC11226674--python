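import numpy as np
import pytest
from skbio import DistanceMatrix

from bioregions import (
    ElbowCurve,
    Regionalization,
    assign_realms,
    delineate_regions,
    elbow,
    evaluate_dendrogram,
    hierarchical_cluster,
    select_algorithm,
    variance_explained_curve,
)
from bioregions.cluster import LINKAGE_ALGORITHMS, UNASSIGNED


def three_cell_dm():
    """d(A,B)=2, d(A,C)=d(B,C)=6 — hand-workable UPGMA case."""
    return DistanceMatrix(
        np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float), ids=["A", "B", "C"]
    )


def ultrametric_dm(n_blocks=3, per_block=4, near=0.2, far=0.8):
    """Blockwise two-level ultrametric distances."""
    n = n_blocks * per_block
    d = np.full((n, n), far)
    for b in range(n_blocks):
        lo, hi = b * per_block, (b + 1) * per_block
        d[lo:hi, lo:hi] = near
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"c{i}" for i in range(n)])


class TestHierarchicalCluster:
    def test_hand_upgma_merge_sequence(self):
        dend = hierarchical_cluster(three_cell_dm(), "UPGMA")
        heights = dend.linkage[:, 2]
        assert heights[0] == pytest.approx(2.0)  # (A,B) first
        assert heights[1] == pytest.approx(6.0)  # then C
        assert set(dend.linkage[0, :2]) == {0.0, 1.0}

    def test_n_minus_one_merges(self):
        dm = ultrametric_dm()
        for method in LINKAGE_ALGORITHMS:
            dend = hierarchical_cluster(dm, method)
            assert dend.linkage.shape[0] == dm.shape[0] - 1

    def test_ultrametric_fixed_point(self):
        dm = ultrametric_dm()
        dend = hierarchical_cluster(dm, "UPGMA")
        assert np.allclose(dend.cophenetic(), dm.condensed_form())

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            hierarchical_cluster(three_cell_dm(), "KMEANS")


class TestEvaluateAndSelect:
    def test_ultrametric_perfect_scores(self):
        dm = ultrametric_dm()
        r, gower = evaluate_dendrogram(hierarchical_cluster(dm, "UPGMA"), dm)
        assert r == pytest.approx(1.0)
        assert gower == pytest.approx(0.0, abs=1e-20)

    def test_hand_three_pair_pearson(self):
        dm = three_cell_dm()
        dend = hierarchical_cluster(dm, "UPGMA")
        r, gower = evaluate_dendrogram(dend, dm)
        # cophenetic vector (2, 6, 6) equals the input exactly
        assert r == pytest.approx(1.0)
        assert gower == pytest.approx(0.0)

    def test_gower_scales_quadratically(self):
        rng = np.random.default_rng(0)
        raw = rng.random((8, 8))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm1 = DistanceMatrix(d)
        dm2 = DistanceMatrix(2 * d)
        _, g1 = evaluate_dendrogram(hierarchical_cluster(dm1, "WARD"), dm1)
        _, g2 = evaluate_dendrogram(hierarchical_cluster(dm2, "WARD"), dm2)
        assert g2 == pytest.approx(4 * g1)

    def test_constant_distances_error(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d)
        dend = hierarchical_cluster(dm, "UPGMA")
        with pytest.raises(ValueError, match="constant"):
            evaluate_dendrogram(dend, dm)

    def test_select_single_algorithm(self):
        assert select_algorithm({"WARD": (0.7, 1.0)}) == "WARD"

    def test_select_highest_correlation(self):
        assert select_algorithm({"UPGMA": (0.9, 5.0), "WARD": (0.7, 1.0)}) == "UPGMA"

    def test_select_tie_broken_by_gower(self):
        assert (
            select_algorithm({"WPGMA": (0.9, 2.0), "UPGMA": (0.9, 1.0)}) == "UPGMA"
        )

    def test_select_empty_errors(self):
        with pytest.raises(ValueError):
            select_algorithm({})


class TestVarianceExplained:
    def test_endpoints(self):
        dm = ultrametric_dm()
        dend = hierarchical_cluster(dm, "UPGMA")
        curve = variance_explained_curve(dm, dend, k_max=dm.shape[0])
        assert curve.variance_explained[0] == pytest.approx(0.0)
        assert curve.variance_explained[-1] == pytest.approx(1.0)

    def test_two_separated_blocks_explained_at_two(self):
        n = 8
        d = np.ones((n, n))
        d[:4, :4] = 0.0
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d)
        dend = hierarchical_cluster(dm, "UPGMA")
        curve = variance_explained_curve(dm, dend, k_max=5)
        assert curve.variance_explained[1] == pytest.approx(1.0)  # k = 2

    def test_nondecreasing_in_k(self):
        rng = np.random.default_rng(5)
        raw = rng.random((15, 15))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d)
        dend = hierarchical_cluster(dm, "UPGMA")
        ve = variance_explained_curve(dm, dend, k_max=15).variance_explained
        assert np.all(np.diff(ve) >= -1e-12)

    def test_all_zero_distances_warns(self):
        dm = DistanceMatrix(np.zeros((5, 5)))
        dend = hierarchical_cluster(dm, "UPGMA")
        with pytest.warns(UserWarning):
            curve = variance_explained_curve(dm, dend, k_max=5)
        assert np.all(curve.variance_explained == 1.0)


class TestElbow:
    def test_chord_distance_case(self):
        curve = ElbowCurve(
            np.array([1, 2, 3, 4, 5]), np.array([0.0, 0.8, 0.85, 0.88, 0.9])
        )
        assert elbow(curve) == 2

    def test_two_block_curve(self):
        n = 8
        d = np.ones((n, n))
        d[:4, :4] = 0.0
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d)
        dend = hierarchical_cluster(dm, "UPGMA")
        assert elbow(variance_explained_curve(dm, dend, k_max=6)) == 2

    def test_linear_curve_falls_back_with_warning(self):
        curve = ElbowCurve(np.arange(1, 6), np.linspace(0, 1, 5))
        with pytest.warns(UserWarning):
            assert elbow(curve) == 2  # smallest interior k

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            elbow(ElbowCurve(np.array([1, 2]), np.array([0.0, 1.0])))


def _block_dm(grid, clusters):
    """Distance 0 within each listed cluster, 1 between clusters."""
    ids = [c for cells in clusters for c in cells]
    n = len(ids)
    lab = {}
    for k, cells in enumerate(clusters):
        for c in cells:
            lab[c] = k
    d = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if lab[ids[i]] == lab[ids[j]]:
                d[i, j] = 0.0
    return DistanceMatrix(d, ids=ids)


class TestDelineateRegions:
    def test_strictly_more_than_min_cells(self, lattice_20x20):
        grid = lattice_20x20
        # contiguous 10-cell cluster (first 10 of row 0) vs the rest
        ten = grid.cell_ids[:10]
        rest = grid.cell_ids[10:]
        dm = _block_dm(grid, [ten, rest])
        dend = hierarchical_cluster(dm, "UPGMA")
        reg = delineate_regions(dend, 2, grid, min_cells=10)
        assert all(reg.region_of_cell[c] == UNASSIGNED for c in ten)
        assert all(reg.region_of_cell[c] != UNASSIGNED for c in rest)

    def test_eleven_contiguous_cells_valid(self, lattice_20x20):
        grid = lattice_20x20
        eleven = grid.cell_ids[:11]
        dm = _block_dm(grid, [eleven, grid.cell_ids[11:]])
        dend = hierarchical_cluster(dm, "UPGMA")
        reg = delineate_regions(dend, 2, grid, min_cells=10)
        assert reg.n_regions == 2

    def test_split_cluster_aggregation_threshold(self, lattice_20x20):
        grid = lattice_20x20
        # 6 cells top-left corner + 6 cells bottom-right corner: two distant
        # components of equal size -> largest-component fraction exactly 0.5
        top = grid.cell_ids[:6]
        bottom = grid.cell_ids[-6:]
        split = top + bottom
        rest = grid.cell_ids[6:-6]
        dm = _block_dm(grid, [split, rest])
        dend = hierarchical_cluster(dm, "UPGMA")
        at_half = delineate_regions(dend, 2, grid, aggregation_threshold=0.5)
        assert all(at_half.region_of_cell[c] != UNASSIGNED for c in split)
        at_06 = delineate_regions(dend, 2, grid, aggregation_threshold=0.6)
        assert all(at_06.region_of_cell[c] == UNASSIGNED for c in split)

    def test_component_fraction_matches_bfs_oracle(self, lattice_20x20):
        from bioregions.cluster import _largest_component_fraction

        grid = lattice_20x20
        cells = grid.cell_ids[:6] + grid.cell_ids[-6:]
        # BFS oracle over the induced adjacency
        cellset = set(cells)
        seen, best = set(), 0
        for start in cells:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                c = stack.pop()
                if c in comp:
                    continue
                comp.add(c)
                stack.extend(m for m in grid.neighbors[c] if m in cellset)
            seen |= comp
            best = max(best, len(comp))
        assert _largest_component_fraction(cells, grid) == pytest.approx(
            best / len(cells)
        )

    def test_missing_grid_cells_error(self, small_grid):
        dm = _block_dm(small_grid, [small_grid.cell_ids])
        dm = DistanceMatrix(dm.data, ids=["zz" + i for i in dm.ids])
        dend = hierarchical_cluster(dm, "UPGMA")
        with pytest.raises(ValueError, match="absent from the grid"):
            delineate_regions(dend, 1, small_grid)


class TestAssignRealms:
    def _hierarchical_case(self, grid):
        """4 planted regions nested in 2 realms via two-level distances."""
        q = grid.n_cells // 4
        quarters = [grid.cell_ids[i * q : (i + 1) * q] for i in range(4)]
        ids = [c for cells in quarters for c in cells]
        lab = np.repeat([0, 1, 2, 3], q)
        d = np.where(
            lab[:, None] == lab[None, :],
            0.1,
            np.where((lab[:, None] // 2) == (lab[None, :] // 2), 0.5, 0.9),
        ).astype(float)
        np.fill_diagonal(d, 0)
        return DistanceMatrix(d, ids=ids), quarters

    def test_realms_nest_regions(self, lattice_20x20):
        dm, quarters = self._hierarchical_case(lattice_20x20)
        dend = hierarchical_cluster(dm, "UPGMA")
        reg = delineate_regions(dend, 4, lattice_20x20)
        reg = assign_realms(dend, reg, dm)
        assert reg.n_regions == 4
        assert len(set(reg.realm_of_region.values())) == 2
        # every region's cells sit in exactly one realm by construction
        for region in reg.regions:
            assert region in reg.realm_of_region

    def test_two_realm_recovery_is_exact(self, lattice_20x20):
        from bioregions import adjusted_rand_index

        dm, quarters = self._hierarchical_case(lattice_20x20)
        dend = hierarchical_cluster(dm, "UPGMA")
        reg = delineate_regions(dend, 4, lattice_20x20)
        reg = assign_realms(dend, reg, dm)
        truth = {}
        for k, cells in enumerate(quarters):
            for c in cells:
                truth[c] = f"realm{k // 2}"
        recovered = {
            c: reg.realm_of_region[reg.region_of_cell[c]]
            for c in reg.valid_cells
        }
        assert adjusted_rand_index(recovered, {c: truth[c] for c in recovered}) == 1.0

    def test_no_valid_regions_errors(self, small_grid):
        dm = _block_dm(small_grid, [small_grid.cell_ids])
        dend = hierarchical_cluster(dm, "UPGMA")
        reg = Regionalization.from_labels(
            {c: UNASSIGNED for c in small_grid.cell_ids}
        )
        with pytest.raises(ValueError, match="no valid regions"):
            assign_realms(dend, reg, dm)
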