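"""Graph construction, modularity (vs. brute force), Louvain, K-selection, merging."""

import itertools

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmahet import clustering
from tmahet.errors import ValidationError

from conftest import brute_force_modularity


def _clique_pair(n=5, weight=1.0):
    """Two disconnected n-cliques."""
    g = ig.Graph()
    g.add_vertices(2 * n)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges += [(i + n, j + n) for i, j in edges]
    g.add_edges(edges)
    g.es["weight"] = [weight] * len(edges)
    return g


class TestKnnGraph:
    def test_separated_clouds_have_no_cross_edges(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.5, (30, 2))
        b = rng.normal(100, 0.5, (30, 2))
        x = np.vstack([a, b])
        g = clustering.knn_graph(x, clustering.ClusteringConfig(K=5))
        for i, j in g.get_edgelist():
            assert (i < 30) == (j < 30)

    def test_k1_collinear_equidistant_points_deterministic(self):
        # points at 0, 1, 2: the middle point's tie breaks to the lower index
        x = np.array([[0.0], [1.0], [2.0]])
        nbrs = clustering.knn_neighbors(x, 1)
        assert nbrs.ravel().tolist() == [1, 0, 1]
        g = clustering.knn_graph(x, clustering.ClusteringConfig(K=1))
        assert sorted(map(tuple, g.get_edgelist())) == [(0, 1), (1, 2)]

    def test_identical_neighbor_sets_give_weight_one(self):
        # coincident pair far from everything: mutual nearest neighbors whose
        # (self-inclusive) neighbor sets coincide -> Jaccard 1
        x = np.array([[0.0], [0.0], [100.0], [101.0]])
        g = clustering.knn_graph(x, clustering.ClusteringConfig(K=1))
        w = {tuple(sorted(e)): wt for e, wt in zip(g.get_edgelist(), g.es["weight"])}
        assert w[(0, 1)] == pytest.approx(1.0)

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValidationError, match="K"):
            clustering.knn_neighbors(np.zeros((5, 2)), 5)

    def test_missing_values_rejected(self):
        x = np.array([[0.0], [np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            clustering.knn_neighbors(x, 1)

    def test_exact_and_approximate_paths_agree(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (60, 3))
        exact = clustering.knn_neighbors(x, 7)
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(60):
            assert set(exact[i]) == set(np.argsort(d2[i])[:7])


class TestModularity:
    def test_all_in_one_partition_is_zero(self):
        g = _clique_pair(4)
        assert clustering.modularity(g, np.zeros(8)) == pytest.approx(0.0)

    def test_singletons_on_clique_closed_form(self):
        # every node its own community on an n-clique: Q = -sum a_i^2 < 0
        n = 6
        g = ig.Graph.Full(n)
        g.es["weight"] = [1.0] * g.ecount()
        q = clustering.modularity(g, np.arange(n))
        assert q == pytest.approx(-n * (1.0 / n) ** 2)
        assert q < 0

    def test_two_cliques_match_brute_force_and_igraph(self):
        g = _clique_pair(5)
        labels = np.array([0] * 5 + [1] * 5)
        q = clustering.modularity(g, labels)
        assert q == pytest.approx(brute_force_modularity(g, labels), abs=1e-12)
        assert q == pytest.approx(g.modularity(labels.tolist(), weights=g.es["weight"]),
                                  abs=1e-12)
        assert q == pytest.approx(0.5)  # e_ii sums to 1, a_i = 1/2 each

    def test_exhaustive_partitions_small_graphs(self):
        # every partition of random weighted graphs up to 6 nodes
        rng = np.random.default_rng(2)
        for n in (3, 4, 5, 6):
            g = ig.Graph.Erdos_Renyi(n=n, p=0.7)
            while g.ecount() == 0:
                g = ig.Graph.Erdos_Renyi(n=n, p=0.9)
            g.es["weight"] = rng.uniform(0.1, 2.0, g.ecount()).tolist()
            for labels in itertools.product(range(n), repeat=n):
                labels = np.array(labels)
                assert clustering.modularity(g, labels) == pytest.approx(
                    brute_force_modularity(g, labels), abs=1e-12)

    def test_wrong_label_length_rejected(self):
        with pytest.raises(ValidationError, match="labels"):
            clustering.modularity(_clique_pair(3), np.zeros(5))

    def test_bounds_on_random_partitions(self):
        rng = np.random.default_rng(3)
        g = ig.Graph.Erdos_Renyi(n=20, p=0.3)
        g.es["weight"] = rng.uniform(0.1, 3.0, g.ecount()).tolist()
        for _ in range(50):
            labels = rng.integers(0, 4, 20)
            assert -1.0 <= clustering.modularity(g, labels) <= 1.0


class TestLouvain:
    def test_disconnected_cliques_recovered(self):
        g = _clique_pair(5)
        res = clustering.louvain(g, seed=0)
        assert res.n_clusters == 2
        assert res.modularity == pytest.approx(brute_force_modularity(g, res.labels),
                                               abs=1e-12)
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(c, 0.3, (40, 2)) for c in (0, 5, 10)])
        cfg = clustering.ClusteringConfig(K=10, seed=11)
        r1 = clustering.cluster_features(x, cfg)
        r2 = clustering.cluster_features(x, cfg)
        assert np.array_equal(r1.labels, r2.labels)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            clustering.louvain(ig.Graph(), seed=0)

    def test_labels_ordered_by_descending_size(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.3, (60, 2)), rng.normal(8, 0.3, (20, 2))])
        res = clustering.cluster_features(x, clustering.ClusteringConfig(K=8, seed=0))
        counts = pd.Series(res.labels).value_counts().sort_index()
        assert (counts.diff().dropna() <= 0).all()

    def test_permutation_equivariance(self):
        # the graph is exactly equivariant; the Louvain sweep is node-order
        # sensitive, so partitions must agree but need not be identical
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(c, 0.3, (30, 2)) for c in (0, 6)])
        perm = rng.permutation(len(x))
        cfg = clustering.ClusteringConfig(K=5, seed=2)
        g_base = clustering.knn_graph(x, cfg)
        g_perm = clustering.knn_graph(x[perm], cfg)
        base_edges = {(min(perm[i], perm[j]), max(perm[i], perm[j])): round(w, 12)
                      for (i, j), w in zip(g_perm.get_edgelist(), g_perm.es["weight"])}
        orig_edges = {(min(i, j), max(i, j)): round(w, 12)
                      for (i, j), w in zip(g_base.get_edgelist(), g_base.es["weight"])}
        assert base_edges == orig_edges
        base = clustering.cluster_features(x, cfg).labels
        permuted = clustering.cluster_features(x[perm], cfg).labels
        assert adjusted_rand_score(base[perm], permuted) >= 0.9


class TestSelectK:
    def test_blob_recovery_with_scan(self):
        rng = np.random.default_rng(7)
        truth = np.repeat([0, 1, 2], 100)
        x = np.vstack([rng.normal(4 * c, 0.4, (100, 2)) for c in range(3)])
        k, res = clustering.select_k(x, clustering.ClusteringConfig(
            K=10, K_scan=(10, 30, 50), seed=0))
        assert k in (10, 30, 50)
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (40, 2))
        k, _ = clustering.select_k(x, clustering.ClusteringConfig(K=5, K_scan=(7,), seed=0))
        assert k == 7

    def test_tie_resolves_to_smallest_k(self, monkeypatch):
        calls = []

        def fake_cluster(features, cfg, names=None):
            calls.append(cfg.K)
            return clustering.ClusterResult(labels=np.zeros(10, dtype=int),
                                            n_clusters=1, modularity=0.42, K=cfg.K)

        monkeypatch.setattr(clustering, "cluster_features", fake_cluster)
        k, res = clustering.select_k(np.zeros((10, 2)), clustering.ClusteringConfig(
            K=3, K_scan=(3, 5, 7), seed=0))
        assert calls == [3, 5, 7]
        assert k == 3  # equal Q everywhere -> smallest K wins


class TestMerge:
    def _result(self, centroids):
        df = pd.DataFrame(centroids)
        df.index.name = "_cluster"
        n = len(df)
        return clustering.ClusterResult(
            labels=np.arange(n), n_clusters=n, modularity=0.5, centroids=df,
            sizes=pd.DataFrame({"n": np.ones(n), "percent": np.full(n, 100.0 / n)}))

    def test_identity_merge(self):
        res = self._result(np.eye(4))
        merge = clustering.merge_clusters(res, 4)
        assert merge.n_groups == 4
        assert len(set(merge.merge_map.values())) == 4

    def test_identical_pair_merges_first(self):
        cent = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        merge = clustering.merge_clusters(self._result(cent), 3)
        assert merge.merge_map[0] == merge.merge_map[1]
        assert len({merge.merge_map[2], merge.merge_map[3], merge.merge_map[0]}) == 3

    def test_noisy_centroids_recover_known_grouping(self):
        # 12 centroids built from 8 base compositions + small noise: cutting
        # at 8 reunites the copies
        rng = np.random.default_rng(9)
        base = rng.dirichlet(np.ones(10), size=8)
        members = [0, 1, 2, 3, 4, 5, 6, 7, 0, 3, 5, 7]
        cent = np.vstack([base[m] + rng.normal(0, 0.005, 10) for m in members])
        merge = clustering.merge_clusters(self._result(cent), 8)
        assert merge.n_groups == 8
        groups = np.array([merge.merge_map[i] for i in range(12)])
        assert adjusted_rand_score(np.array(members), groups) == 1.0

    def test_invalid_group_counts_rejected(self):
        res = self._result(np.eye(3))
        with pytest.raises(ValidationError, match="n_groups"):
            clustering.merge_clusters(res, 0)
        with pytest.raises(ValidationError, match="n_groups"):
            clustering.merge_clusters(res, 4)


def test_archetype_recovery_moderate_n():
    """Cells from well-separated expression archetypes are recovered exactly."""
    from tmahet import panels, preprocess, synthetic

    df, truth = synthetic.simulate_archetype_cells(1200, seed=13)
    normed, _ = preprocess.normalize(df.assign(core_id="c"),
                                     preprocess.NormalizationConfig(panel=panels.IHC4))
    feats = normed[[panels.norm_col(m) for m in panels.IHC4_MARKERS]].to_numpy()
    res = clustering.cluster_features(feats, clustering.ClusteringConfig(K=100, seed=1))
    assert res.n_clusters == 5
    assert adjusted_rand_score(truth, res.labels) >= 0.9
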