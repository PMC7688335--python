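"""Cell-level kNN graph, Louvain partitions, graph abstraction and layout.

The differentiation landscape is summarized as in partition-based graph
abstraction (PAGA): a symmetrized k = 7 nearest-neighbor graph over cells,
fine and coarse Louvain partitions of that graph, and an abstracted graph
whose nodes are fine clusters and whose edge weights compare observed
inter-cluster edge counts to the expectation under random edge placement,

    w_ij = min(1, e_ij / e_hat_ij),   e_hat_ij = E_total * n_i n_j / sum_{a<b} n_a n_b.

Node positions come from a simplified ForceAtlas2-style layout: linear
attraction along (weighted) edges, degree-scaled repulsion between all node
pairs.  Layouts are visualization-only; no analysis value depends on them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import igraph as ig
import leidenalg
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph",
    "AbstractGraph",
    "build_knn_graph",
    "louvain_partition",
    "paga_connectivity",
    "force_layout",
    "node_mean_expression",
]


@dataclass
class NeighborGraph:
    edges: np.ndarray  # (n_edges, 2) int, i < j, symmetrized union kNN
    n_cells: int
    k: int

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(n=self.n_cells, edges=[tuple(e) for e in self.edges])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


def build_knn_graph(embedding: np.ndarray, k: int = 7) -> NeighborGraph:
    """Undirected union-symmetrized kNN graph (edge if either endpoint lists
    the other among its k nearest; self-edges excluded; distance ties broken
    by index order)."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    pairs = set()
    for i in range(n):
        # exclude the cell itself, keep exactly k neighbors (duplicate
        # coordinates may push self out of the returned list)
        neigh = [int(j) for j in idx[i] if j != i][:k]
        for j in neigh:
            pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=np.int64)
    return NeighborGraph(edges=edges, n_cells=n, k=k)


def louvain_partition(graph: NeighborGraph, resolution: float = 1.0,
                      seed: int = 0) -> np.ndarray:
    """Modularity community detection (Leiden refinement of Louvain, seeded).

    Returns integer labels, relabeled to descending community size.
    """
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.array(part.membership)
    # stable relabel: by size desc, then smallest member index
    ids, counts = np.unique(labels, return_counts=True)
    first = [int(np.where(labels == i)[0][0]) for i in ids]
    order = sorted(range(len(ids)), key=lambda t: (-counts[t], first[t]))
    remap = {ids[t]: r for r, t in enumerate(order)}
    return np.array([remap[l] for l in labels])


@dataclass
class AbstractGraph:
    node_ids: np.ndarray        # fine-cluster labels
    sizes: np.ndarray           # member counts, sum to n_cells
    weights: np.ndarray         # (n_nodes, n_nodes) symmetric, in [0, 1]
    members: dict               # node id -> cell index array
    layout: np.ndarray | None = None
    node_values: dict = field(default_factory=dict)  # name -> per-node array

    def edges_above(self, threshold: float):
        """(i, j, weight) triples with weight strictly above the threshold."""
        out = []
        n = len(self.node_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > threshold:
                    out.append((i, j, float(self.weights[i, j])))
        return out

    def neighbors_above(self, node_id, threshold: float):
        i = int(np.where(self.node_ids == node_id)[0][0])
        return [
            self.node_ids[j]
            for j in range(len(self.node_ids))
            if j != i and self.weights[i, j] > threshold
        ]

    def to_json(self, path: str, edge_threshold: float = 0.0) -> None:
        nodes = []
        for i, nid in enumerate(self.node_ids):
            node = {"id": str(nid), "size": int(self.sizes[i])}
            if self.layout is not None:
                node["x"], node["y"] = map(float, self.layout[i])
            for name, vals in self.node_values.items():
                node[name] = float(vals[i])
            nodes.append(node)
        edges = [
            {"source": str(self.node_ids[i]), "target": str(self.node_ids[j]),
             "weight": w}
            for i, j, w in self.edges_above(edge_threshold)
        ]
        with open(path, "w") as fh:
            json.dump({"nodes": nodes, "edges": edges}, fh, indent=1)


def paga_connectivity(graph: NeighborGraph, fine_labels) -> AbstractGraph:
    """Abstracted graph with observed/expected edge-count connectivities."""
    fine_labels = np.asarray(fine_labels, dtype=object)
    if len(fine_labels) != graph.n_cells:
        raise ValueError("labels must cover all cells in the graph")
    node_ids = np.array(sorted(set(fine_labels.tolist())), dtype=object)
    if len(node_ids) < 2:
        raise ValueError("need at least 2 fine clusters for abstraction")
    code = {l: i for i, l in enumerate(node_ids)}
    lab = np.array([code[l] for l in fine_labels])
    n_nodes = len(node_ids)
    sizes = np.bincount(lab, minlength=n_nodes)
    e_obs = np.zeros((n_nodes, n_nodes))
    a = lab[graph.edges[:, 0]]
    b = lab[graph.edges[:, 1]]
    inter = a != b
    np.add.at(e_obs, (a[inter], b[inter]), 1)
    np.add.at(e_obs, (b[inter], a[inter]), 1)
    e_total = len(graph.edges)
    nn = np.outer(sizes, sizes).astype(float)
    # expected inter-cluster edge count under uniformly random edge placement
    # over all cell pairs: E_total * n_i n_j / C(n_cells, 2)
    n = float(graph.n_cells)
    denom = n * (n - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        e_hat = e_total * nn / denom
        w = np.where(e_hat > 0, np.minimum(1.0, e_obs / np.maximum(e_hat, 1e-300)), 0.0)
    np.fill_diagonal(w, 0.0)
    members = {nid: np.where(lab == i)[0] for i, nid in enumerate(node_ids)}
    return AbstractGraph(node_ids=node_ids, sizes=sizes, weights=w, members=members)


def force_layout(n_nodes: int, edges, weights=None, iterations: int = 300,
                 seed: int = 0) -> np.ndarray:
    """Simplified ForceAtlas2 layout: linear edge attraction, degree-scaled
    all-pairs repulsion, decaying step size.  Deterministic given seed."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    if n_nodes == 1:
        return np.zeros((1, 2))
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    w = np.ones(len(edges)) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    pos = rng.normal(scale=0.1, size=(n_nodes, 2))
    deg = np.zeros(n_nodes)
    if len(edges):
        np.add.at(deg, edges[:, 0], w)
        np.add.at(deg, edges[:, 1], w)
    for it in range(iterations):
        step = 0.05 * (1.0 - it / iterations) + 0.005
        delta = pos[:, None, :] - pos[None, :, :]
        d2 = (delta ** 2).sum(axis=2) + 1e-9
        rep = ((deg + 1)[:, None] * (deg + 1)[None, :])[:, :, None] * delta / d2[:, :, None]
        force = 0.05 * rep.sum(axis=1)
        if len(edges):
            diff = pos[edges[:, 1]] - pos[edges[:, 0]]
            pull = w[:, None] * diff
            np.add.at(force, edges[:, 0], pull)
            np.add.at(force, edges[:, 1], -pull)
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        force = np.where(norm > 10.0, force * 10.0 / norm, force)
        pos += step * force
    if not np.isfinite(pos).all():
        raise FloatingPointError("layout produced non-finite coordinates")
    return pos - pos.mean(axis=0)


def node_mean_expression(norm_X, gene_ids, fine_labels, gene_id) -> dict:
    """Mean normalized expression of one gene over the member cells of each node."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    hit = np.where(gene_ids == gene_id)[0]
    if len(hit) == 0:
        near = [g for g in gene_ids if str(gene_id).lower() in str(g).lower()][:5]
        raise KeyError(f"gene {gene_id!r} not found; nearest ids: {near}")
    col = hit[0]
    vals = norm_X[:, col]
    vals = np.asarray(vals.todense()).ravel() if hasattr(vals, "todense") else np.asarray(vals).ravel()
    fine_labels = np.asarray(fine_labels, dtype=object)
    return {
        nid: float(vals[fine_labels == nid].mean())
        for nid in sorted(set(fine_labels.tolist()))
    }
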