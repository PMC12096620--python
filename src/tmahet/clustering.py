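"""PhenoGraph-style graph clustering.

Cells (or image patches) are embedded by their feature vectors, connected to
their K nearest Euclidean neighbors, and the directed KNN edges are
symmetrized by union. Each edge is weighted by the Jaccard index of the two
endpoints' neighbor sets, so edges between points whose neighborhoods
disagree are down-weighted. Communities are found by Louvain modularity
maximization; partition quality is the weighted Newman–Girvan modularity

    Q = sum_c [ w_in(c)/m − (s(c)/(2m))² ],    Q ∈ [−1, 1],

with m the total edge weight, w_in(c) the within-community weight and s(c)
the community's total node strength. The neighbor count K is selected by
scanning candidates and keeping the partition with maximal Q.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

log = logging.getLogger(__name__)

#: default neighbor counts: 300 for cell co-expression, 30 for patch niches
K_CELLS = 300
K_PATCHES = 30

DEFAULT_K_SCAN = (15, 30, 50, 100, 150, 300)


@dataclass(frozen=True)
class ClusteringConfig:
    K: int = K_CELLS
    K_scan: tuple[int, ...] = DEFAULT_K_SCAN
    weighting: str = "jaccard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.weighting not in ("jaccard", "binary"):
            raise ValidationError(f"weighting must be 'jaccard' or 'binary', got {self.weighting!r}")
        if len(self.K_scan) == 0:
            raise ValidationError("K_scan must be non-empty")


@dataclass
class ClusterResult:
    """A partition with its quality and per-cluster profiles.

    Cluster ids are 0-based and ordered by descending size.
    """

    labels: np.ndarray
    n_clusters: int
    modularity: float
    centroids: pd.DataFrame | None = None
    sizes: pd.Series | None = None
    K: int | None = None


@dataclass
class MergeResult:
    """Fine clusters aggregated into phenotype groups by average linkage."""

    linkage: np.ndarray
    merge_map: dict[int, int]
    group_names: dict[int, str]
    n_groups: int


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def knn_neighbors(features: np.ndarray, K: int) -> np.ndarray:
    """Indices of each row's K nearest Euclidean neighbors (self excluded).

    Distance ties are broken by item index, ascending, so the graph is
    deterministic.
    """
    x = np.asarray(features, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("features contain missing values")
    n = x.shape[0]
    if K >= n:
        raise ValidationError(f"K must be < number of items ({n}), got {K}")
    if n <= 2048:
        # exact distances; lexsort gives the stated (distance, index) tie-break
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        idx = np.tile(np.arange(n), (n, 1))
        order = np.lexsort((idx, d2), axis=1)
        return order[:, :K]
    nn = NearestNeighbors(n_neighbors=K + 1).fit(x)
    dist, ind = nn.kneighbors(x)
    out = np.empty((n, K), dtype=np.int64)
    for i in range(n):
        cand_d, cand_i = dist[i], ind[i]
        keep = cand_i != i
        cand_d, cand_i = cand_d[keep], cand_i[keep]
        order = np.lexsort((cand_i, cand_d))
        out[i] = cand_i[order][:K]
    return out


def knn_graph(features: np.ndarray, cfg: ClusteringConfig) -> ig.Graph:
    """Weighted undirected KNN graph (union symmetrization).

    Under ``weighting='jaccard'`` the edge (i, j) carries the Jaccard index
    of the two K-neighbor sets (each set includes the node itself, so
    mutually nearest points with a shared neighborhood reach weight 1);
    under ``'binary'`` all edges weigh 1. Zero-Jaccard edges are dropped
    (their endpoints share no neighborhood).
    """
    nbrs = knn_neighbors(features, cfg.K)
    n, K = nbrs.shape
    rows = np.concatenate([np.repeat(np.arange(n), K), np.arange(n)])
    cols = np.concatenate([nbrs.ravel(), np.arange(n)])  # self included
    A = csr_matrix((np.ones(n * (K + 1), dtype=np.int32), (rows, cols)), shape=(n, n))
    U = ((A + A.T) > 0).tocoo()
    mask = U.row < U.col  # also drops self-loops from the union
    ei, ej = U.row[mask], U.col[mask]
    if cfg.weighting == "binary":
        w = np.ones(len(ei))
    else:
        inter = np.asarray((A @ A.T)[ei, ej]).ravel()
        union = 2.0 * (K + 1) - inter
        w = inter / union
        keep = w > 0
        ei, ej, w = ei[keep], ej[keep], w[keep]
    g = ig.Graph(n=n, edges=list(zip(ei.tolist(), ej.tolist())), directed=False)
    g.es["weight"] = w.tolist()
    return g


# ---------------------------------------------------------------------------
# modularity and Louvain
# ---------------------------------------------------------------------------

def modularity(graph: ig.Graph, labels: np.ndarray) -> float:
    """Weighted Newman–Girvan modularity of a labelled partition."""
    labels = np.asarray(labels)
    if len(labels) != graph.vcount():
        raise ValidationError(
            f"labels cover {len(labels)} nodes but graph has {graph.vcount()}")
    if graph.ecount() == 0:
        raise ValidationError("graph has no edges; modularity undefined")
    w = np.asarray(graph.es["weight"] if "weight" in graph.es.attributes()
                   else np.ones(graph.ecount()), dtype=float)
    edges = np.asarray(graph.get_edgelist())
    m = w.sum()
    _, lab = np.unique(labels, return_inverse=True)
    ncom = lab.max() + 1
    within = np.zeros(ncom)
    same = lab[edges[:, 0]] == lab[edges[:, 1]]
    np.add.at(within, lab[edges[:, 0]][same], w[same])
    strength = np.zeros(ncom)
    np.add.at(strength, lab[edges[:, 0]], w)
    np.add.at(strength, lab[edges[:, 1]], w)
    return float((within / m - (strength / (2.0 * m)) ** 2).sum())


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """0-based labels ordered by descending cluster size (ties: first seen)."""
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    first_seen = np.zeros(len(uniq), dtype=np.int64)
    seen_order = pd.unique(labels)
    for rank, v in enumerate(seen_order):
        first_seen[np.searchsorted(uniq, v)] = rank
    order = np.lexsort((first_seen, -counts))
    remap = np.empty(len(uniq), dtype=np.int64)
    remap[order] = np.arange(len(uniq))
    return remap[inv]


def louvain(graph: ig.Graph, seed: int = 0,
            features: np.ndarray | None = None,
            feature_names: list[str] | None = None,
            K: int | None = None) -> ClusterResult:
    """Louvain community detection with seeded, reproducible refinement."""
    if graph.vcount() == 0:
        raise ValidationError("empty graph")
    ig.set_random_number_generator(random.Random(seed))
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = graph.community_multilevel(weights=weights)
    labels = _relabel_by_size(np.asarray(part.membership))
    q = modularity(graph, labels) if graph.ecount() else 0.0
    centroids = sizes = None
    if features is not None:
        fdf = pd.DataFrame(np.asarray(features, dtype=float), columns=feature_names)
        fdf["_cluster"] = labels
        centroids = fdf.groupby("_cluster").mean()
        counts = pd.Series(labels).value_counts().sort_index()
        sizes = pd.DataFrame({"n": counts, "percent": 100.0 * counts / counts.sum()})
    return ClusterResult(labels=labels, n_clusters=int(labels.max()) + 1,
                         modularity=q, centroids=centroids, sizes=sizes, K=K)


def cluster_features(features: np.ndarray, cfg: ClusteringConfig,
                     feature_names: list[str] | None = None) -> ClusterResult:
    """KNN graph + Louvain in one step."""
    g = knn_graph(features, cfg)
    return louvain(g, seed=cfg.seed, features=features,
                   feature_names=feature_names, K=cfg.K)


def select_k(features: np.ndarray, cfg: ClusteringConfig,
             feature_names: list[str] | None = None) -> tuple[int, ClusterResult]:
    """Scan candidate K and keep the partition with maximal modularity.

    Modularity values computed on different graphs are not directly
    comparable (sparser KNN graphs carry inflated Q), so every candidate
    partition is scored on one common reference graph, built at the largest
    scanned K. Candidates are capped at n−1 and deduplicated; ties resolve
    to the smallest K. The scan table is logged.
    """
    n = np.asarray(features).shape[0]
    candidates = sorted({min(k, n - 1) for k in cfg.K_scan if k >= 1})
    if not candidates:
        raise ValidationError("K_scan contains no valid candidates")
    ref_graph = knn_graph(features, ClusteringConfig(
        K=candidates[-1], weighting=cfg.weighting, seed=cfg.seed))
    best_k, best, best_q = None, None, -np.inf
    for k in candidates:
        res = cluster_features(features, ClusteringConfig(
            K=k, weighting=cfg.weighting, seed=cfg.seed), feature_names)
        q_ref = modularity(ref_graph, res.labels)
        log.info("select_k: K=%d -> %d clusters, Q_own=%.4f, Q_ref=%.4f",
                 k, res.n_clusters, res.modularity, q_ref)
        if q_ref > best_q:
            best_k, best, best_q = k, res, q_ref
    return best_k, best


# ---------------------------------------------------------------------------
# cluster aggregation
# ---------------------------------------------------------------------------

def merge_clusters(result: ClusterResult, n_groups: int,
                   name_features: bool = True) -> MergeResult:
    """Aggregate fine clusters into groups by average-linkage on centroids.

    The tree over cluster centroid vectors is cut to exactly ``n_groups``;
    each group is named after the dominant feature of its (size-weighted)
    mean profile.
    """
    if n_groups < 1:
        raise ValidationError(f"n_groups must be >= 1, got {n_groups}")
    if result.centroids is None:
        raise ValidationError("ClusterResult has no centroids; cluster with features")
    n_clusters = result.n_clusters
    if n_groups > n_clusters:
        raise ValidationError(f"n_groups ({n_groups}) exceeds n_clusters ({n_clusters})")
    cent = result.centroids.sort_index()
    if n_clusters == 1:
        merge_map = {0: 0}
        Z = np.empty((0, 4))
    else:
        Z = linkage(cent.to_numpy(), method="average", metric="euclidean")
        flat = fcluster(Z, t=n_groups, criterion="maxclust")
        # relabel groups by order of first appearance for stability
        remap: dict[int, int] = {}
        for g in flat:
            if g not in remap:
                remap[g] = len(remap)
        merge_map = {int(c): remap[g] for c, g in zip(cent.index, flat)}

    names: dict[int, str] = {}
    if name_features:
        sizes = (result.sizes["n"] if result.sizes is not None
                 else pd.Series(1.0, index=cent.index))
        for g in sorted(set(merge_map.values())):
            members = [c for c, gg in merge_map.items() if gg == g]
            w = sizes.loc[members].to_numpy(dtype=float)
            profile = (cent.loc[members].to_numpy() * w[:, None]).sum(0) / w.sum()
            names[g] = _group_name(pd.Series(profile, index=cent.columns))
        # disambiguate duplicates deterministically
        seen: dict[str, int] = {}
        for g in sorted(names):
            base = names[g]
            seen[base] = seen.get(base, 0) + 1
            if seen[base] > 1:
                names[g] = f"{base} ({seen[base]})"
    else:
        names = {g: f"group_{g}" for g in sorted(set(merge_map.values()))}
    return MergeResult(linkage=Z, merge_map=merge_map, group_names=names,
                       n_groups=len(set(merge_map.values())))


def _group_name(profile: pd.Series) -> str:
    """Human-readable group name from the dominant composition feature."""
    top = str(profile.idxmax())
    top_val = float(profile.max())
    if top == "CK+":
        return "cancer only" if top_val >= 0.6 else "cancer mixed"
    if top_val < 0.25:
        return "Immune rich"
    return f"{top} rich"
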