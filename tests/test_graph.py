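import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mklandscape import datagen, graph, mapping, qc


def brute_force_knn_edges(X, k):
    D = cdist(X, X)
    n = len(X)
    pairs = set()
    for i in range(n):
        order = [j for j in np.argsort(D[i], kind="stable") if j != i][:k]
        for j in order:
            pairs.add((min(i, j), max(i, j)))
    return pairs


class TestBuildKnnGraph:
    def test_collinear_points_symmetrize(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        g = graph.build_knn_graph(pts, k=1)
        edges = {tuple(e) for e in g.edges}
        assert (0, 1) in edges and (1, 2) in edges

    def test_equals_brute_force_on_random_points(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        g = graph.build_knn_graph(X, k=7)
        assert {tuple(e) for e in g.edges} == brute_force_knn_edges(X, 7)

    def test_duplicate_coordinates_not_an_error(self):
        X = np.zeros((10, 3))
        g = graph.build_knn_graph(X, k=2)
        assert g.n_cells == 10 and len(g.edges) > 0
        assert (g.edges[:, 0] != g.edges[:, 1]).all()  # no self-edges

    def test_k_bound(self):
        with pytest.raises(ValueError, match="k="):
            graph.build_knn_graph(np.zeros((5, 2)), k=5)


class TestLouvainPartition:
    def _two_cliques(self, n=10):
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        edges += [(i + n, j + n) for i, j in edges]
        return graph.NeighborGraph(edges=np.array(edges), n_cells=2 * n, k=n - 1)

    @pytest.mark.parametrize("resolution", [0.2, 0.5, 1.0])
    def test_disconnected_cliques_split_exactly(self, resolution):
        g = self._two_cliques()
        labels = graph.louvain_partition(g, resolution, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 4))
        g = graph.build_knn_graph(X, k=7)
        l1 = graph.louvain_partition(g, 1.0, seed=42)
        l2 = graph.louvain_partition(g, 1.0, seed=42)
        assert np.array_equal(l1, l2)

    def test_planted_blobs_recovered_over_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        ok = 0
        for s in range(10):
            clusters = [datagen.ClusterSpec(f"c{i}", 1 / 13) for i in range(13)]
            spec = datagen.LandscapeSpec(
                n_genes=300, n_mito_genes=10, coarse_clusters=clusters,
                fine_per_coarse=1, latent_dim=13, cluster_separation=10.0,
                nb_dispersion=0.2, library_size_mean=2000,
                n_reference_cells=1300, seed=s,
            )
            cm, truth = datagen.generate_reference(spec)
            norm = qc.normalize_total(cm, 2000.0)
            hvgs = mapping.select_hvgs(norm, cm.gene_ids, n_hvgs=200)
            model = mapping.fit_pca(norm, cm.gene_ids, hvgs, n_components=30, seed=s)
            emb = mapping.project(norm, cm.gene_ids, model)
            labels = graph.louvain_partition(graph.build_knn_graph(emb, k=7),
                                             0.3, seed=s)
            ok += adjusted_rand_score(truth.coarse_label, labels) >= 0.95
        assert ok >= 9


class TestPagaConnectivity:
    def test_all_internal_edges_give_zero_weight(self):
        n = 8
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        edges += [(i + n, j + n) for i, j in edges]
        g = graph.NeighborGraph(edges=np.array(edges), n_cells=2 * n, k=n - 1)
        labels = np.array(["a"] * n + ["b"] * n, dtype=object)
        ag = graph.paga_connectivity(g, labels)
        assert ag.weights[0, 1] == 0.0

    def test_random_graph_balanced_split_weight_near_one(self):
        # Under random edge placement the observed/expected ratio centers on 1
        rng = np.random.default_rng(3)
        n = 60
        vals = []
        for _ in range(50):
            mask = rng.random((n, n)) < 0.15
            edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                              if mask[i, j]])
            g = graph.NeighborGraph(edges=edges, n_cells=n, k=0)
            labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
            ag = graph.paga_connectivity(g, labels)
            # raw observed/expected before the clip at 1
            e_obs = sum(1 for i, j in edges if (i < n // 2) != (j < n // 2))
            e_hat = len(edges) * (n // 2) * (n // 2) / (n * (n - 1) / 2)
            vals.append(e_obs / e_hat)
        assert abs(np.mean(vals) - 1.0) < 0.02

    def test_weights_symmetric_bounded_and_sizes_conserve_cells(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 3))
        X[60:, 0] += 4.0
        g = graph.build_knn_graph(X, k=7)
        labels = np.array([f"n{i % 4}" for i in range(120)], dtype=object)
        ag = graph.paga_connectivity(g, labels)
        assert ag.sizes.sum() == 120
        np.testing.assert_allclose(ag.weights, ag.weights.T)
        assert (ag.weights >= 0).all() and (ag.weights <= 1).all()
        assert np.diag(ag.weights).sum() == 0

    def test_cell_duplication_leaves_weights_stable(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 4))
        X[40:, 0] += 3
        g = graph.build_knn_graph(X, k=5)
        labels = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        ag = graph.paga_connectivity(g, labels)
        # duplicate every cell; replicate each edge across the four copy pairs
        e = g.edges
        n = g.n_cells
        e2 = np.vstack([e, e + n, np.stack([e[:, 0], e[:, 1] + n], 1),
                        np.stack([e[:, 0] + n, e[:, 1]], 1)])
        e2 = np.array(sorted({(min(a, b), max(a, b)) for a, b in e2}))
        g2 = graph.NeighborGraph(edges=e2, n_cells=2 * n, k=5)
        ag2 = graph.paga_connectivity(g2, np.concatenate([labels, labels]))
        np.testing.assert_allclose(ag2.weights, ag.weights, atol=0.05)

    def test_display_filter_is_strict_threshold(self):
        w = np.array([[0.0, 0.3, 0.8], [0.3, 0.0, 0.1], [0.8, 0.1, 0.0]])
        ag = graph.AbstractGraph(
            node_ids=np.array(["a", "b", "c"], dtype=object),
            sizes=np.array([2, 2, 2]), weights=w,
            members={l: np.arange(2) for l in "abc"},
        )
        assert ag.edges_above(0.3) == [(0, 2, 0.8)]  # 0.3 itself excluded

    def test_singleton_clusters_allowed(self):
        g = graph.NeighborGraph(edges=np.array([[0, 1], [1, 2]]), n_cells=3, k=1)
        labels = np.array(["a", "b", "c"], dtype=object)
        ag = graph.paga_connectivity(g, labels)
        assert ag.weights.shape == (3, 3)


class TestForceLayout:
    def test_single_node_at_origin(self):
        np.testing.assert_array_equal(graph.force_layout(1, []), [[0.0, 0.0]])

    def test_deterministic_and_finite(self):
        edges = [(0, 1), (1, 2), (2, 0), (3, 4)]
        p1 = graph.force_layout(5, edges, seed=7)
        p2 = graph.force_layout(5, edges, seed=7)
        np.testing.assert_array_equal(p1, p2)
        assert np.isfinite(p1).all()

    def test_disconnected_cliques_separate(self):
        n = 6
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        edges += [(i + n, j + n) for i, j in edges]
        ok = 0
        for s in range(10):
            pos = graph.force_layout(2 * n, edges, seed=s)
            intra = np.mean([np.linalg.norm(pos[i] - pos[j])
                             for i, j in edges])
            inter = np.mean([np.linalg.norm(pos[i] - pos[j + n])
                             for i in range(n) for j in range(n)])
            ok += inter > intra
        assert ok == 10


class TestNodeMeanExpression:
    def test_constant_node_value(self):
        X = np.array([[2.0, 1.0], [2.0, 5.0], [7.0, 3.0]])
        ids = np.array(["gA", "gB"], dtype=object)
        labels = np.array(["n1", "n1", "n2"], dtype=object)
        means = graph.node_mean_expression(X, ids, labels, "gA")
        assert means == {"n1": 2.0, "n2": 7.0}

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(4, size=(50, 6)).astype(float)
        ids = np.array([f"g{j}" for j in range(6)], dtype=object)
        labels = np.array([f"n{i % 5}" for i in range(50)], dtype=object)
        means = graph.node_mean_expression(X, ids, labels, "g3")
        import pandas as pd

        oracle = pd.DataFrame({"v": X[:, 3], "l": labels}).groupby("l")["v"].mean()
        for node, val in means.items():
            assert val == pytest.approx(oracle[node])

    def test_unknown_gene_suggests_neighbors(self):
        X = np.ones((4, 3))
        ids = np.array(["Pf4", "Vwf", "Mpl"], dtype=object)
        labels = np.array(["n"] * 4, dtype=object)
        with pytest.raises(KeyError, match="Pf4"):
            graph.node_mean_expression(X, ids, labels, "pf4")
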