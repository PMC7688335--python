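"""Reference PCA space and k-nearest-neighbor label transfer.

The reference sample defines the embedding: highly variable genes are selected
by mean-binned normalized dispersion on log1p-transformed, total-count
normalized data; the selected genes are centered (optionally unit-scaled with
clipping) and decomposed into the top 50 principal components.  Query cells
are projected with the reference's centering/scaling/loadings — reference
statistics are never recomputed from the query — and each query cell takes the
label held by the plurality of its 15 nearest reference cells (Euclidean
distance in component space), with ties broken by summed inverse distance and
then by label order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PCAModel",
    "ClusterAssignment",
    "select_hvgs",
    "fit_pca",
    "project",
    "assign_clusters_knn",
]


def _dense_log1p(X) -> np.ndarray:
    if sp.issparse(X):
        X = X.toarray()
    return np.log1p(np.asarray(X, dtype=np.float64))


def select_hvgs(norm_X, gene_ids, n_hvgs: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Select highly variable genes by binned normalized dispersion.

    Works on log1p of the normalized matrix.  Genes are binned by mean
    expression (``n_bins`` equal-frequency bins); within each bin the
    dispersion (variance/mean) is z-scored, and the top ``n_hvgs`` genes by
    this normalized dispersion are returned in a deterministic order
    (descending dispersion, gene id as tie-break).
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    E = _dense_log1p(norm_X)
    mean = E.mean(axis=0)
    var = E.var(axis=0)
    # tolerance guards against float noise making constant columns "vary"
    informative = var > 1e-12 * np.maximum(mean, 1.0) ** 2
    n_inf = int(informative.sum())
    if n_inf < n_hvgs:
        raise ValueError(
            f"only {n_inf} genes have nonzero variance; cannot select {n_hvgs}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    norm_disp = np.full(len(gene_ids), -np.inf)
    inf_order = order[informative[order]]
    bins = np.array_split(inf_order, min(n_bins, n_inf))
    for bin_idx in bins:
        d = disp[bin_idx]
        sd = d.std()
        norm_disp[bin_idx] = (d - d.mean()) / (sd if sd > 0 else 1.0)
    # deterministic ranking: dispersion desc, then gene id
    rank = sorted(np.where(informative)[0],
                  key=lambda i: (-norm_disp[i], gene_ids[i]))
    return gene_ids[np.array(rank[:n_hvgs])]


@dataclass
class PCAModel:
    hvg_gene_ids: np.ndarray
    center: np.ndarray          # per-HVG mean of log1p normalized data
    scale: np.ndarray           # per-HVG SD (ones if scaling disabled)
    loadings: np.ndarray        # genes x components, column-orthonormal
    explained_variance: np.ndarray
    n_components: int
    clip: float

    def transform(self, E_hvg: np.ndarray) -> np.ndarray:
        Z = (E_hvg - self.center) / self.scale
        np.clip(Z, -self.clip, self.clip, out=Z)
        return Z @ self.loadings


def fit_pca(norm_X, gene_ids, hvgs, n_components: int = 50,
            scale_unit_variance: bool = True, clip: float = 10.0,
            seed: int = 0) -> PCAModel:
    """Fit the reference PCA model on the HVG submatrix of log1p data."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    hvgs = np.asarray(hvgs, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in hvgs if g not in pos]
    if missing:
        raise ValueError(f"HVGs absent from reference genes: {missing[:5]}")
    cols = np.array([pos[g] for g in hvgs])
    E = _dense_log1p(norm_X)[:, cols]
    n_cells = E.shape[0]
    if n_components > min(n_cells, len(hvgs)):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_hvgs)="
            f"{min(n_cells, len(hvgs))}"
        )
    center = E.mean(axis=0)
    sd = E.std(axis=0)
    if scale_unit_variance:
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} HVGs are constant after centering; "
                "left unscaled"
            )
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones_like(sd)
    Z = (E - center) / scale
    np.clip(Z, -clip, clip, out=Z)
    solver = "full" if min(Z.shape) <= 500 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    pca.fit(Z)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PCAModel(
        hvg_gene_ids=hvgs,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        n_components=n_components,
        clip=clip,
    )


def project(norm_X, gene_ids, model: PCAModel,
            max_missing_fraction: float = 0.2) -> np.ndarray:
    """Project query cells into the reference component space.

    HVGs absent from the query gene axis are treated as all-zero, provided no
    more than ``max_missing_fraction`` of the model's HVGs are missing.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in model.hvg_gene_ids if g not in pos]
    if len(missing) > max_missing_fraction * len(model.hvg_gene_ids):
        raise ValueError(
            f"{len(missing)}/{len(model.hvg_gene_ids)} HVGs missing from query "
            f"(limit {max_missing_fraction:.0%})"
        )
    E = _dense_log1p(norm_X)
    out = np.zeros((E.shape[0], len(model.hvg_gene_ids)))
    for j, g in enumerate(model.hvg_gene_ids):
        if g in pos:
            out[:, j] = E[:, pos[g]]
    return model.transform(out)


@dataclass
class ClusterAssignment:
    labels: np.ndarray        # assigned label per query cell
    label_order: np.ndarray   # label universe, sorted
    tallies: np.ndarray       # query cells x labels vote counts
    tie: np.ndarray           # True when plurality was not unique
    k: int


def assign_clusters_knn(query_emb: np.ndarray, ref_emb: np.ndarray,
                        ref_labels, k: int = 15) -> ClusterAssignment:
    """Plurality vote of the k nearest reference cells per query cell."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > ref_emb.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref_emb.shape[0]}")
    if query_emb.shape[1] != ref_emb.shape[1]:
        raise ValueError("query and reference embeddings have different widths")
    ref_labels = np.asarray(ref_labels, dtype=object)
    label_order = np.array(sorted(set(ref_labels.tolist())), dtype=object)
    lab_idx = {l: i for i, l in enumerate(label_order)}
    code = np.array([lab_idx[l] for l in ref_labels])
    nn = NearestNeighbors(n_neighbors=k).fit(ref_emb)
    dist, idx = nn.kneighbors(query_emb)
    nq, nl = query_emb.shape[0], len(label_order)
    tallies = np.zeros((nq, nl), dtype=np.int32)
    neigh_codes = code[idx]
    for j in range(k):
        np.add.at(tallies, (np.arange(nq), neigh_codes[:, j]), 1)
    # inverse-distance mass per label for tie-breaking
    w = 1.0 / (dist + 1e-12)
    weight = np.zeros((nq, nl))
    for j in range(k):
        np.add.at(weight, (np.arange(nq), neigh_codes[:, j]), w[:, j])
    best = tallies.max(axis=1, keepdims=True)
    is_top = tallies == best
    tie = is_top.sum(axis=1) > 1
    # among tied labels: max inverse-distance weight, then label order
    masked_w = np.where(is_top, weight, -np.inf)
    winner = masked_w.argmax(axis=1)
    labels = label_order[winner]
    return ClusterAssignment(
        labels=labels, label_order=label_order, tallies=tallies, tie=tie, k=k
    )
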