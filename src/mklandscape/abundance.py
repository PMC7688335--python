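"""kNN-vote differential abundance between two query samples.

Every query cell casts votes to its k nearest reference cells, with the total
number of votes given out by each sample equalized.  The default "weighted"
scheme realizes the equal-totals contract exactly: a cell in sample s casts
total mass 1/n_s, split equally over its k nearest reference cells, so each
sample distributes unit mass overall.  The "integer" scheme casts one unit
vote per neighbor with a per-sample k_s = round(V / n_s), which equalizes
totals only up to rounding.  Per reference cell, the signed difference
d = votes(mutant) - votes(wild type) is a descriptive differential-abundance
proxy (positive = enriched in the mutant); node-level summaries average d
over the member cells of each abstract-graph node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "VoteResult",
    "NodeAbundance",
    "cast_votes",
    "abundance_difference",
    "node_abundance",
    "top_enriched_node",
    "node_permutation_null",
]


@dataclass
class VoteResult:
    votes: dict            # sample name -> per-reference-cell vote mass
    scheme: str            # "weighted" or "integer"
    k_by_sample: dict      # sample name -> k used
    n_by_sample: dict      # sample name -> query sample size


def _neighbor_matrix(query_emb, ref_emb, k) -> sp.csr_matrix:
    """Sparse (n_query x n_ref) matrix with 1/k at each cell's k nearest."""
    nn = NearestNeighbors(n_neighbors=k).fit(ref_emb)
    _, idx = nn.kneighbors(query_emb)
    nq = query_emb.shape[0]
    rows = np.repeat(np.arange(nq), k)
    data = np.full(nq * k, 1.0 / k)
    return sp.csr_matrix(
        (data, (rows, idx.ravel())), shape=(nq, ref_emb.shape[0])
    )


def cast_votes(query_embs: dict, ref_emb: np.ndarray, k: int = 15,
               scheme: str = "weighted", total_votes: float | None = None) -> VoteResult:
    """Tally vote mass received by each reference cell from each sample.

    Parameters
    ----------
    query_embs
        Mapping sample name -> query embedding (same component space as
        ``ref_emb``).
    k
        Neighbors per query cell (weighted scheme) or the baseline used to
        set ``total_votes = k * max(n_s)`` for the integer scheme.
    scheme
        ``"weighted"``: per-cell mass 1/n_s split over k neighbors; sample
        totals are exactly 1.  ``"integer"``: k_s = round(V/n_s) unit votes
        per cell, V = ``total_votes``.
    """
    if k <= 0 or k > ref_emb.shape[0]:
        raise ValueError(f"k={k} outside [1, n_reference]")
    if scheme not in ("weighted", "integer"):
        raise ValueError(f"unknown scheme {scheme!r}")
    votes, k_by, n_by = {}, {}, {}
    if scheme == "integer" and total_votes is None:
        total_votes = k * max(q.shape[0] for q in query_embs.values())
    for name, emb in query_embs.items():
        n_s = emb.shape[0]
        if n_s == 0:
            raise ValueError(f"sample {name!r} is empty")
        if emb.shape[1] != ref_emb.shape[1]:
            raise ValueError(f"sample {name!r}: embedding width mismatch")
        if scheme == "weighted":
            M = _neighbor_matrix(emb, ref_emb, k)
            votes[name] = np.asarray(M.sum(axis=0)).ravel() / n_s
            k_by[name] = k
        else:
            k_s = max(1, int(round(total_votes / n_s)))
            k_s = min(k_s, ref_emb.shape[0])
            M = _neighbor_matrix(emb, ref_emb, k_s)
            votes[name] = np.asarray(M.sum(axis=0)).ravel() * k_s  # unit votes
            k_by[name] = k_s
        n_by[name] = n_s
    return VoteResult(votes=votes, scheme=scheme, k_by_sample=k_by, n_by_sample=n_by)


def abundance_difference(result: VoteResult, mutant: str = "MUT",
                         wildtype: str = "WT") -> np.ndarray:
    """Signed per-reference-cell difference d = votes(mutant) - votes(WT)."""
    for name in (mutant, wildtype):
        if name not in result.votes:
            raise KeyError(f"sample {name!r} missing from vote result")
    return result.votes[mutant] - result.votes[wildtype]


@dataclass
class NodeAbundance:
    node_ids: np.ndarray
    mean_d: np.ndarray
    sizes: np.ndarray
    rank: np.ndarray  # rank order, descending mean_d


def node_abundance(d: np.ndarray, fine_labels) -> NodeAbundance:
    """Mean differential abundance of the cells belonging to each node."""
    fine_labels = np.asarray(fine_labels, dtype=object)
    if len(fine_labels) != len(d):
        raise ValueError("labels must cover all reference cells")
    node_ids = np.array(sorted(set(fine_labels.tolist())), dtype=object)
    mean_d = np.array([d[fine_labels == nid].mean() for nid in node_ids])
    sizes = np.array([(fine_labels == nid).sum() for nid in node_ids])
    order = sorted(range(len(node_ids)), key=lambda i: (-mean_d[i], -sizes[i]))
    rank = np.empty(len(node_ids), dtype=int)
    for r, i in enumerate(order):
        rank[i] = r
    return NodeAbundance(node_ids=node_ids, mean_d=mean_d, sizes=sizes, rank=rank)


def top_enriched_node(na: NodeAbundance):
    """Node with maximal mean d; ties broken by node size descending.

    Returns ``(node_id, mean_d, tie_flag)``.
    """
    if len(na.node_ids) == 0:
        raise ValueError("no nodes")
    best = na.mean_d.max()
    tied = np.where(na.mean_d == best)[0]
    tie = len(tied) > 1
    i = tied[np.argmax(na.sizes[tied])]
    return na.node_ids[i], float(na.mean_d[i]), tie


def node_permutation_null(query_embs: dict, ref_emb: np.ndarray, fine_labels,
                          k: int = 15, n_permutations: int = 200, seed: int = 0,
                          mutant: str = "MUT", wildtype: str = "WT",
                          quantile: float = 0.95):
    """Permutation null for |node mean d| by shuffling sample labels.

    Query cells from both samples are pooled; for each permutation the sample
    assignment is shuffled (preserving sample sizes) and the node-level
    |mean d| recomputed.  Returns ``(observed NodeAbundance, per-node null
    quantiles)``.  The neighbor structure is computed once, so permutations
    cost only sparse matrix-vector products.
    """
    fine_labels = np.asarray(fine_labels, dtype=object)
    emb_a, emb_b = query_embs[wildtype], query_embs[mutant]
    n_a, n_b = emb_a.shape[0], emb_b.shape[0]
    pooled = np.vstack([emb_a, emb_b])
    M = _neighbor_matrix(pooled, ref_emb, k)
    is_b = np.zeros(n_a + n_b, dtype=bool)
    is_b[n_a:] = True
    node_ids = np.array(sorted(set(fine_labels.tolist())), dtype=object)
    # normalized group-indicator matrix: (G @ d)[i] = mean of d over node i
    code = {l: i for i, l in enumerate(node_ids)}
    lab = np.array([code[l] for l in fine_labels])
    sizes = np.bincount(lab, minlength=len(node_ids)).astype(float)
    G = sp.csr_matrix(
        (1.0 / sizes[lab], (lab, np.arange(len(lab)))),
        shape=(len(node_ids), len(lab)),
    )

    def node_means(mask_b):
        s = np.where(mask_b, 1.0 / mask_b.sum(), -1.0 / (~mask_b).sum())
        return G @ (s @ M)

    obs = node_means(is_b)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(node_ids)))
    for p in range(n_permutations):
        null[p] = np.abs(node_means(rng.permutation(is_b)))
    return node_ids, obs, np.quantile(null, quantile, axis=0)
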