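"""Graph construction: adjacency from edge lists, Laplacian, coarsening."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from tauspread.connectome import (
    BrainNetwork,
    RegionTable,
    build_laplacian,
    coarsen_network,
    load_default_network,
    make_synthetic_connectome,
    read_edge_list,
    write_edge_list,
)
from tauspread.errors import DataError


def brute_force_laplacian(A: np.ndarray) -> np.ndarray:
    """Independent oracle: elementwise L = D - A with explicit loops."""
    n = A.shape[0]
    L = np.zeros_like(A)
    for i in range(n):
        for j in range(n):
            if i == j:
                L[i, j] = sum(A[i, k] for k in range(n) if k != i)
            else:
                L[i, j] = -A[i, j]
    return L


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = rng.uniform(0.1, 5.0)
    return A


class TestBuildLaplacian:
    def test_two_node_identity_case(self):
        D, L = build_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.array_equal(L, [[1.0, -1.0], [-1.0, 1.0]])
        assert np.array_equal(D, np.eye(2))

    def test_zero_adjacency_gives_zero_laplacian(self):
        D, L = build_laplacian(np.zeros((4, 4)))
        assert not L.any() and not D.any()

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            A = random_adjacency(rng, int(rng.integers(2, 12)))
            _, L = build_laplacian(A)
            # identical up to summation order of the degree entries
            assert np.abs(L - brute_force_laplacian(A)).max() < 1e-12

    def test_row_and_column_sums_vanish(self):
        rng = np.random.default_rng(3)
        A = random_adjacency(rng, 9)
        _, L = build_laplacian(A)
        assert np.abs(L.sum(axis=0)).max() < 1e-12
        assert np.abs(L.sum(axis=1)).max() < 1e-12

    def test_positive_semidefinite_with_constant_null_vector(self):
        rng = np.random.default_rng(7)
        A = random_adjacency(rng, 5)
        _, L = build_laplacian(A)
        w, v = np.linalg.eigh(L)
        assert w.min() >= -1e-10
        ground = v[:, np.argmin(np.abs(w))]
        assert np.allclose(ground / ground[0], np.ones(5))

    def test_zero_eigenvalue_count_equals_connected_components(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = random_adjacency(rng, int(rng.integers(3, 12)), p=0.25)
            _, L = build_laplacian(A)
            n_zero = int(np.sum(np.linalg.eigvalsh(L) < 1e-9))
            g = nx.from_numpy_array(A)
            assert n_zero == nx.number_connected_components(g)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.0], [2.0, 0.0]]),  # asymmetric
            np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative weight
            np.array([[1.0, 1.0], [1.0, 0.0]]),  # self-loop
        ],
    )
    def test_invalid_adjacency_rejected(self, bad):
        with pytest.raises(DataError):
            build_laplacian(bad)


class TestEdgeList:
    @pytest.fixture
    def regions(self):
        return RegionTable(("A", "B", "C"), ("left", "left", "right"),
                           np.array([True, True, False]))

    def write(self, tmp_path, text):
        p = tmp_path / "edges.csv"
        p.write_text(text)
        return p

    def test_weight_is_fiber_count_over_length(self, tmp_path, regions):
        p = self.write(tmp_path,
                       "region_i,region_j,fiber_count,mean_fiber_length\nA,B,10,5\n")
        net = read_edge_list(p, regions)
        assert net.adjacency[0, 1] == net.adjacency[1, 0] == 2.0
        assert net.edge_count == 1

    def test_empty_edge_file_gives_zero_network(self, tmp_path, regions):
        p = self.write(tmp_path, "region_i,region_j,fiber_count,mean_fiber_length\n")
        net = read_edge_list(p, regions)
        assert not net.adjacency.any() and not net.laplacian.any()

    def test_triangle_laplacian_matches_hand_calculation(self, tmp_path, regions):
        p = self.write(tmp_path,
                       "region_i,region_j,fiber_count,mean_fiber_length\n"
                       "A,B,1,1\nB,C,2,1\nA,C,3,1\n")
        net = read_edge_list(p, regions)
        np.testing.assert_array_equal(
            net.laplacian, brute_force_laplacian(net.adjacency)
        )
        np.testing.assert_array_equal(np.diag(net.degree), [4.0, 3.0, 5.0])

    def test_tab_delimited_and_id_references(self, tmp_path, regions):
        p = self.write(tmp_path,
                       "region_i\tregion_j\tfiber_count\tmean_fiber_length\n0\t2\t6\t3\n")
        net = read_edge_list(p, regions)
        assert net.adjacency[0, 2] == 2.0

    @pytest.mark.parametrize(
        "rows,match",
        [
            ("A,Z,1,1\n", "unknown region"),
            ("A,B,1,0\n", "length"),
            ("A,B,1,-2\n", "length"),
            ("A,B,1,1\nB,A,2,1\n", "duplicate"),
            ("A,A,1,1\n", "self-edge"),
        ],
    )
    def test_malformed_edges_rejected(self, tmp_path, regions, rows, match):
        p = self.write(
            tmp_path, "region_i,region_j,fiber_count,mean_fiber_length\n" + rows
        )
        with pytest.raises(DataError, match=match):
            read_edge_list(p, regions)

    def test_round_trip_through_writer(self, tmp_path, regions):
        p = self.write(tmp_path,
                       "region_i,region_j,fiber_count,mean_fiber_length\n"
                       "A,B,10,5\nB,C,4,2\n")
        net = read_edge_list(p, regions)
        out = tmp_path / "out.csv"
        write_edge_list(net, out)
        net2 = read_edge_list(out, regions)
        np.testing.assert_allclose(net2.adjacency, net.adjacency)


class TestCoarsen:
    def fine_network(self, tmp_path, rows):
        names = tuple("abcdef"[: len(set(sum(([r[0], r[1]] for r in rows), [])))])
        # simpler: fixed 6-node table
        regions = RegionTable(tuple("abcdef"), ("left",) * 6, np.ones(6, bool))
        text = "region_i,region_j,fiber_count,mean_fiber_length\n" + "".join(
            f"{i},{j},{n},{l}\n" for i, j, n, l in rows
        )
        p = tmp_path / "fine.csv"
        p.write_text(text)
        return read_edge_list(p, regions)

    def test_parallel_fibers_sum(self, tmp_path):
        # two fine nodes (a, b) both connected to c with n=1, l=1; collapse
        # {a,b} -> region 0, {c} -> region 1: coarse edge n=2, l=1, weight 2
        fine = self.fine_network(tmp_path, [("a", "c", 1, 1), ("b", "c", 1, 1)])
        mapping = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 2, "f": 2}
        coarse = coarsen_network(fine, mapping)
        assert coarse.fiber_count[0, 1] == 2
        assert coarse.fiber_length[0, 1] == 1
        assert coarse.adjacency[0, 1] == 2.0

    def test_identity_map_preserves_network(self, tmp_path):
        fine = self.fine_network(tmp_path, [("a", "b", 3, 2), ("c", "d", 5, 4)])
        coarse = coarsen_network(fine, {n: i for i, n in enumerate("abcdef")},
                                 coarse_regions=fine.regions)
        np.testing.assert_allclose(coarse.adjacency, fine.adjacency)

    def test_aggregation_matches_hand_enumeration(self, tmp_path):
        rows = [("a", "c", 2, 1.0), ("a", "d", 4, 3.0), ("b", "d", 6, 2.0),
                ("c", "d", 1, 1.0), ("e", "f", 8, 2.0)]
        fine = self.fine_network(tmp_path, rows)
        mapping = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2}
        coarse = coarsen_network(fine, mapping)
        # group 0 <-> group 1 edges: (a,c,2,1), (a,d,4,3), (b,d,6,2)
        assert coarse.fiber_count[0, 1] == 12
        expected_len = (2 * 1.0 + 4 * 3.0 + 6 * 2.0) / 12
        assert coarse.fiber_length[0, 1] == pytest.approx(expected_len)
        assert coarse.adjacency[0, 1] == pytest.approx(12 / expected_len)
        # intra-group edges dropped: (c,d) and (e,f)
        assert coarse.adjacency[1, 1] == 0
        assert coarse.adjacency[2, 2] == 0
        assert coarse.fiber_count[0, 2] == 0

    def test_unmapped_node_rejected(self, tmp_path):
        fine = self.fine_network(tmp_path, [("a", "b", 1, 1)])
        with pytest.raises(DataError, match="unmapped"):
            coarsen_network(fine, {"a": 0, "b": 0})


class TestRegionTable:
    def test_contiguous_ids_enforced(self):
        import pandas as pd

        df = pd.DataFrame({"region_id": [0, 2], "name": ["a", "b"],
                           "hemisphere": ["left", "right"], "is_cortical": [1, 0]})
        with pytest.raises(DataError, match="contiguous"):
            RegionTable.from_frame(df)

    def test_lookup_by_name_and_id(self):
        rt = RegionTable(("x", "y"), ("left", "right"), np.array([True, False]))
        assert rt.index("y") == 1 and rt.index(0) == 0
        assert list(rt.cortical_indices) == [0]
        with pytest.raises(DataError, match="unknown region"):
            rt.index("nope")

    def test_csv_round_trip(self, tmp_path):
        rt = RegionTable(("x", "y"), ("left", "right"), np.array([True, False]))
        rt.to_csv(tmp_path / "r.csv")
        rt2 = RegionTable.read_csv(tmp_path / "r.csv")
        assert rt2.names == rt.names and (rt2.is_cortical == rt.is_cortical).all()


class TestDefaultNetwork:
    def test_packaged_synthetic_connectome_shape(self):
        net = load_default_network()
        assert net.n == 83
        assert net.regions.cortical_indices.size == 66
        assert np.abs(net.laplacian.sum(axis=1)).max() < 1e-12
        assert np.linalg.eigvalsh(net.laplacian).min() >= -1e-10

    def test_interhemispheric_connectivity_is_sparse(self):
        net = load_default_network()
        hemi = np.array([h == "left" for h in net.regions.hemisphere])
        left, right = np.flatnonzero(hemi), np.flatnonzero(~hemi)
        cross = net.adjacency[np.ix_(left, right)]
        within = net.adjacency[np.ix_(left, left)]
        assert np.count_nonzero(cross) / cross.size < np.count_nonzero(within) / within.size

    def test_generator_is_deterministic(self):
        r1, e1 = make_synthetic_connectome(seed=7)
        r2, e2 = make_synthetic_connectome(seed=7)
        assert r1.names == r2.names
        assert e1.equals(e2)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=15), st.integers(min_value=0, max_value=10**6))
def test_laplacian_psd_property(n, seed):
    """L = D - A is PSD with zero row sums for any nonnegative symmetric A."""
    A = random_adjacency(np.random.default_rng(seed), n)
    _, L = build_laplacian(A)
    assert np.abs(L.sum(axis=1)).max() < 1e-12
    assert np.linalg.eigvalsh(L).min() >= -1e-10
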