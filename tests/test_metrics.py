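import numpy as np
import pytest

from pediconn.metrics import (
    characteristic_path_length,
    compute_global_metrics,
    compute_nodal_metrics,
    global_efficiency,
    group_hubs,
    identify_hubs,
    local_efficiency,
    network_strength,
    nodal_efficiency,
    shortest_path_matrix,
)

from conftest import floyd_warshall_oracle, make_connectome, random_graph, tiny_cohort


class TestClosedForms:
    """Hand-derived values on the 3-node path (w=4) and K4 (w=2)."""

    def test_path_shortest_paths(self, path_abc):
        L = shortest_path_matrix(path_abc)
        assert L[0, 1] == pytest.approx(0.25)
        assert L[1, 2] == pytest.approx(0.25)
        assert L[0, 2] == pytest.approx(0.5)
        assert np.all(np.diag(L) == 0)

    def test_k4_all_pairs_direct(self, k4_uniform):
        L = shortest_path_matrix(k4_uniform)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(L[off], 0.5)

    def test_k4_globals(self, k4_uniform):
        assert global_efficiency(k4_uniform) == pytest.approx(2.0)
        assert characteristic_path_length(k4_uniform) == pytest.approx(0.5)
        assert local_efficiency(k4_uniform) == pytest.approx(2.0)
        assert network_strength(k4_uniform) == pytest.approx(6.0)

    def test_path_globals(self, path_abc):
        # pairs (A,B),(B,C),(A,C): inverse lengths 4, 4, 2
        assert global_efficiency(path_abc) == pytest.approx(10 / 3)
        assert characteristic_path_length(path_abc) == pytest.approx(1 / 3)
        assert local_efficiency(path_abc) == pytest.approx(0.0)
        assert network_strength(path_abc) == pytest.approx(16 / 3)

    def test_path_nodal_efficiency(self, path_abc):
        e = nodal_efficiency(path_abc)
        assert e == pytest.approx([3.0, 4.0, 3.0])

    def test_two_disconnected_dyads(self):
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 1
        w[2, 3] = w[3, 2] = 1
        conn = make_connectome(w)
        # only 4 ordered reachable pairs contribute, each 1/L = 1
        assert global_efficiency(conn) == pytest.approx(1 / 3)
        assert characteristic_path_length(conn) == pytest.approx(1.0)

    def test_empty_graph_lp_undefined(self):
        conn = make_connectome(np.zeros((3, 3), dtype=int))
        assert np.isnan(characteristic_path_length(conn))
        assert network_strength(conn) == 0.0


class TestOracleEquivalence:
    """Randomized equivalence with an exhaustive Floyd-Warshall oracle."""

    @pytest.mark.parametrize("seed", range(4))
    def test_shortest_paths_match_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            w = random_graph(rng, n, density=float(rng.uniform(0.2, 0.9)))
            L = shortest_path_matrix(make_connectome(w))
            assert np.allclose(L, floyd_warshall_oracle(w), rtol=1e-9, atol=0, equal_nan=True)

    def test_efficiencies_match_oracle_derived_values(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            w = random_graph(rng, n, density=0.5)
            conn = make_connectome(w)
            L = floyd_warshall_oracle(w)
            off = ~np.eye(n, dtype=bool)
            inv = np.where(np.isfinite(L) & off & (L > 0), 1.0 / np.where(L > 0, L, 1), 0.0)
            assert global_efficiency(conn) == pytest.approx(inv[off].sum() / (n * (n - 1)), rel=1e-9)
            assert nodal_efficiency(conn) == pytest.approx(inv.sum(axis=1) / (n - 1), rel=1e-9)

    def test_local_efficiency_matches_bruteforce_subgraphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            w = random_graph(rng, n, density=0.6)
            expected = 0.0
            for i in range(n):
                nbrs = np.flatnonzero(w[i] > 0)
                if nbrs.size < 2:
                    continue
                sub = w[np.ix_(nbrs, nbrs)]
                Ls = floyd_warshall_oracle(sub)
                m = nbrs.size
                offm = ~np.eye(m, dtype=bool)
                invs = np.where(np.isfinite(Ls) & offm & (Ls > 0), 1.0 / np.where(Ls > 0, Ls, 1), 0)
                expected += invs[offm].sum() / (m * (m - 1))
            assert local_efficiency(make_connectome(w)) == pytest.approx(expected / n, rel=1e-9)

    def test_networkx_cross_check(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = random_graph(rng, 8, density=0.5)
            g = nx.from_numpy_array(1.0 / np.where(w > 0, w, np.inf))
            g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True) if not np.isfinite(d["weight"])])
            L = shortest_path_matrix(make_connectome(w))
            for i, dists in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
                for j, d in dists.items():
                    assert L[i, j] == pytest.approx(d, rel=1e-9)


class TestInvariants:
    def test_mean_nodal_efficiency_equals_global_efficiency(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            w = random_graph(rng, int(rng.integers(3, 10)), density=0.5)
            conn = make_connectome(w)
            assert nodal_efficiency(conn).mean() == pytest.approx(global_efficiency(conn), rel=1e-9)

    def test_weight_scaling_laws(self):
        """Scaling all weights by c scales efficiencies and strength by c
        and Lp by 1/c."""
        rng = np.random.default_rng(5)
        w = random_graph(rng, 7, density=0.7)
        conn, scaled = make_connectome(w), make_connectome(3 * w)
        assert global_efficiency(scaled) == pytest.approx(3 * global_efficiency(conn))
        assert local_efficiency(scaled) == pytest.approx(3 * local_efficiency(conn))
        assert network_strength(scaled) == pytest.approx(3 * network_strength(conn))
        assert np.allclose(nodal_efficiency(scaled), 3 * nodal_efficiency(conn))
        assert characteristic_path_length(scaled) == pytest.approx(characteristic_path_length(conn) / 3)

    def test_adding_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            w = random_graph(rng, 6, density=0.4)
            conn = make_connectome(w)
            iu, ju = np.triu_indices(6, k=1)
            zeros = [(i, j) for i, j in zip(iu, ju) if w[i, j] == 0]
            if not zeros:
                continue
            i, j = zeros[int(rng.integers(len(zeros)))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = int(rng.integers(1, 20))
            L1, L2 = shortest_path_matrix(conn), shortest_path_matrix(make_connectome(w2))
            assert global_efficiency(w2) >= global_efficiency(w) - 1e-12
            finite = np.isfinite(L1)
            assert np.all(L2[finite] <= L1[finite] + 1e-12)


class TestHubs:
    def test_hand_calculated_threshold(self):
        """E_nodal {3,4,3}: mean 3.333, sample sd 0.577, threshold 3.911."""
        hs = identify_hubs(np.array([3.0, 4.0, 3.0]))
        assert hs.hubs == (1,)
        assert hs.threshold == pytest.approx(10 / 3 + np.std([3, 4, 3], ddof=1))

    def test_single_outlier_hub(self):
        hs = identify_hubs(np.array([1.0, 1.0, 1.0, 1.0, 10.0]))
        assert hs.hubs == (4,)

    def test_all_equal_degenerate_returns_all(self):
        hs = identify_hubs(np.array([2.0, 2.0, 2.0]))
        assert hs.hubs == (0, 1, 2)

    def test_group_hubs_on_average_network(self):
        cohort = tiny_cohort(n_nodes=6, planted_edge=(0, 1), gap=200, base=10)
        hs = group_hubs(cohort, "ASD", sparsity=0.5)
        assert set(hs.hubs) <= set(range(6))
        assert len(hs.hubs) >= 1


class TestTables:
    def test_metric_tables_schema(self):
        from pediconn.metrics import global_metrics_table, nodal_metrics_table

        cohort = tiny_cohort()
        gm = global_metrics_table(cohort)
        assert list(gm.columns) == ["subject_id", "group", "age", "strength", "Eg", "Eloc", "Lp"]
        assert len(gm) == len(cohort)
        nm = nodal_metrics_table(cohort)
        assert len(nm) == len(cohort) * 5
        assert {"E_nodal", "strength", "node", "hemisphere"} <= set(nm.columns)

    def test_global_metrics_dataclass(self, k4_uniform):
        gm = compute_global_metrics(k4_uniform)
        assert gm.as_dict() == {"strength": 6.0, "Eg": 2.0, "Eloc": 2.0, "Lp": 0.5}
        nm = compute_nodal_metrics(k4_uniform)
        assert np.allclose(nm.e_nodal, 2.0)
        assert np.allclose(nm.strength, 6.0)
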