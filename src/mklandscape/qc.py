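"""Quality control: doublet simulation/scoring, hard filters, normalization.

Doublet detection follows the synthetic-doublet strategy: synthetic profiles
are element-wise sums of random pairs of observed cells; observed and
synthetic cells are jointly total-count normalized, log-transformed and
embedded by PCA, and each observed cell is scored by the fraction of its k
nearest neighbors that are synthetic.  The top-scoring 1% (LSK gate) / 4.5%
(LK gate) of cells per sample are removed.  Hard filters then remove cells
with >10% mitochondrial UMIs, fewer than 500 detected genes, or a total UMI
count further than 3 SDs from the per-sample mean; remaining cells are scaled
to a common total count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix
from .config import PipelineConfig

__all__ = [
    "DoubletScores",
    "QcReport",
    "simulate_doublets",
    "doublet_scores",
    "remove_top_doublets",
    "qc_filter",
    "normalize_total",
    "run_qc",
]


@dataclass
class DoubletScores:
    scores: np.ndarray  # per observed cell, in [0, 1]
    n_synthetic: int
    n_pcs: int
    k: int
    embedding: np.ndarray = None  # joint PCA coords (observed then synthetic)


@dataclass
class QcReport:
    """Retained-cell accounting per sample x gate.

    Cells removed by several rules are counted once, by the first applicable
    rule in the order: doublet score, mitochondrial fraction, detected genes,
    total-UMI outlier.
    """

    table: pd.DataFrame  # columns: sample, gate, n_input, n_removed_*, n_retained
    umi_stats: dict      # (sample, gate) -> (mean, sd) totals used by the 3-SD rule

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def simulate_doublets(cm: CountMatrix, n_synthetic: int | None = None,
                      seed: int = 0) -> CountMatrix:
    """Element-wise sums of two distinct randomly sampled cells.

    Defaults to one synthetic profile per observed cell, keeping the two
    classes of the downstream neighbor classifier balanced.
    """
    n = cm.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to simulate doublets")
    if n_synthetic is None:
        n_synthetic = n
    if n_synthetic <= 0:
        raise ValueError("n_synthetic must be positive")
    rng = np.random.default_rng(seed)
    a = rng.integers(n, size=n_synthetic)
    b = rng.integers(n - 1, size=n_synthetic)
    b[b >= a] += 1  # distinct parents, uniform over ordered pairs
    X = cm.X[a] + cm.X[b]
    return CountMatrix(
        X=X,
        barcodes=np.array([f"SYNTH-{i:06d}" for i in range(n_synthetic)], dtype=object),
        gene_ids=cm.gene_ids,
        gene_is_mito=cm.gene_is_mito,
        sample=np.array(["SYNTH"] * n_synthetic, dtype=object),
        gate=np.array(["SYNTH"] * n_synthetic, dtype=object),
    )


def doublet_scores(cm: CountMatrix, synthetic: CountMatrix, n_pcs: int = 30,
                   k: int = 20, seed: int = 0) -> DoubletScores:
    """Score each observed cell by its synthetic-neighbor fraction in PCA space."""
    if not np.array_equal(cm.gene_ids, synthetic.gene_ids):
        raise ValueError("observed and synthetic matrices must share the gene axis")
    if synthetic.n_cells == 0:
        raise ValueError("no synthetic profiles provided")
    n_total = cm.n_cells + synthetic.n_cells
    if k >= n_total:
        raise ValueError(f"k={k} must be smaller than the joint cell count {n_total}")
    joint = sp.vstack([cm.X, synthetic.X]).tocsr().astype(np.float64)
    totals = np.asarray(joint.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cell in doublet scoring input")
    target = float(np.median(totals))
    joint = sp.diags(target / totals) @ joint
    E = np.log1p(joint.toarray())
    n_comp = min(n_pcs, E.shape[0] - 1, E.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(E - E.mean(axis=0, keepdims=True))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[: cm.n_cells])
    neigh = idx[:, 1:]  # first neighbor is the cell itself
    is_synth = neigh >= cm.n_cells
    return DoubletScores(
        scores=is_synth.mean(axis=1),
        n_synthetic=synthetic.n_cells,
        n_pcs=n_comp,
        k=k,
        embedding=emb,
    )


def remove_top_doublets(scores: DoubletScores, cm: CountMatrix,
                        fraction_by_gate: dict) -> np.ndarray:
    """Boolean mask of retained cells after per-sample x gate doublet removal.

    Within each sample x gate group, the ``ceil(fraction * n)`` cells with the
    highest scores are removed; ties at the cutoff break by (score desc,
    barcode asc) for determinism.
    """
    n = cm.n_cells
    if len(scores.scores) != n:
        raise ValueError("scores and matrix cell counts differ")
    keep = np.ones(n, dtype=bool)
    for (sample, gate), idx in _group_indices(cm):
        if gate not in fraction_by_gate:
            raise ValueError(f"unknown gate label {gate!r} (no removal fraction)")
        frac = fraction_by_gate[gate]
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"fraction for gate {gate!r} outside [0, 1)")
        n_remove = math.ceil(frac * len(idx)) if frac > 0 else 0
        if n_remove == 0:
            continue
        order = sorted(idx, key=lambda i: (-scores.scores[i], cm.barcodes[i]))
        keep[order[:n_remove]] = False
    return keep


def _group_indices(cm: CountMatrix):
    df = pd.DataFrame({"sample": cm.sample, "gate": cm.gate})
    for key, sub in df.groupby(["sample", "gate"], sort=True):
        yield key, sub.index.to_numpy()


def qc_filter(cm: CountMatrix, config: PipelineConfig,
              umi_stats: dict | None = None):
    """Apply the three hard QC rules; returns ``(filtered, QcReport)``.

    Rules, in bookkeeping order: mitochondrial fraction strictly above
    ``mito_fraction_max``; detected genes strictly below ``min_genes``; total
    UMI count further than ``umi_sd_bound`` SDs from the mean (both tails).
    UMI mean/SD are computed per sample x gate on raw totals by default;
    pass ``umi_stats`` to reuse statistics frozen from an earlier pass.
    """
    totals = cm.totals().astype(float)
    t = np.log1p(totals) if config.umi_rule_log else totals
    mito_bad = cm.mito_fraction() > config.mito_fraction_max
    genes_bad = cm.genes_detected() < config.min_genes
    umi_bad = np.zeros(cm.n_cells, dtype=bool)
    stats_out = {}
    if config.umi_rule_pooled:
        groups = [(("all", "all"), np.arange(cm.n_cells))]
    else:
        groups = list(_group_indices(cm))
    for key, idx in groups:
        if umi_stats is not None and key in umi_stats:
            mean, sd = umi_stats[key]
        else:
            mean, sd = float(np.mean(t[idx])), float(np.std(t[idx]))
        stats_out[key] = (mean, sd)
        umi_bad[idx] = np.abs(t[idx] - mean) > config.umi_sd_bound * sd

    rows = []
    removed = np.zeros(cm.n_cells, dtype=bool)
    for (sample, gate), idx in _group_indices(cm):
        m = mito_bad[idx]
        g = genes_bad[idx] & ~m
        u = umi_bad[idx] & ~m & ~genes_bad[idx]
        rows.append(
            {
                "sample": sample,
                "gate": gate,
                "n_input": len(idx),
                "n_removed_doublet": 0,
                "n_removed_mito": int(m.sum()),
                "n_removed_genes": int(g.sum()),
                "n_removed_umi_outlier": int(u.sum()),
                "n_retained": int(len(idx) - (m | g | u).sum()),
            }
        )
        removed[idx] = m | g | u
    if removed.all():
        raise ValueError("QC removed every cell; check thresholds and input")
    report = QcReport(table=pd.DataFrame(rows), umi_stats=stats_out)
    return cm.subset_cells(~removed), report


def normalize_total(cm: CountMatrix, target: float) -> sp.csr_matrix:
    """Scale each cell so its total equals ``target`` (real-valued output)."""
    totals = cm.totals().astype(float)
    if (totals == 0).any():
        bad = cm.barcodes[totals == 0][:5].tolist()
        raise ValueError(f"zero-total cells cannot be normalized: {bad}")
    return (sp.diags(target / totals) @ cm.X.astype(np.float64)).tocsr()


def run_qc(cm: CountMatrix, config: PipelineConfig, seed: int = 0):
    """Full QC for one sample: doublet removal then hard filters.

    Returns ``(filtered CountMatrix, QcReport, DoubletScores, kept_mask)``.
    """
    synth = simulate_doublets(cm, seed=seed)
    scores = doublet_scores(cm, synth, n_pcs=config.doublet_n_pcs,
                            k=config.doublet_k, seed=seed)
    keep = remove_top_doublets(scores, cm, config.doublet_removal_fraction)
    n_doublet_removed = pd.DataFrame(
        {"sample": cm.sample[~keep], "gate": cm.gate[~keep]}
    ).groupby(["sample", "gate"]).size()
    filtered, report = qc_filter(cm.subset_cells(np.where(keep)[0]), config)
    for key, n_rm in n_doublet_removed.items():
        sel = (report.table["sample"] == key[0]) & (report.table["gate"] == key[1])
        report.table.loc[sel, "n_removed_doublet"] = int(n_rm)
        report.table.loc[sel, "n_input"] += int(n_rm)
    return filtered, report, scores, keep
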