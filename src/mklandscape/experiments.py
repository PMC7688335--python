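"""Benchmark experiments on synthetic landscapes.

Self-contained trial functions used by the analysis scripts, the acceptance
checks and the test suite.  Each trial builds its inputs from the generator,
runs the relevant pipeline stages, and returns the measured outcome; nothing
is cached between trials and every source of randomness is seeded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import abundance, datagen, de, graph, mapping, qc
from .config import PipelineConfig

__all__ = [
    "bridge_recovery_trial",
    "doublet_auroc_trial",
    "de_recovery_trial",
    "null_calibration_trial",
    "qc_contract_counts",
    "printed_statistics",
]


@dataclass
class BridgeTrialResult:
    top_is_bridge: bool
    flanks_connected: bool
    n_fine_clusters: int
    top_node: str


def bridge_recovery_trial(seed: int, n_reference_cells: int = 5000,
                          n_query_cells: int = 3000,
                          config: PipelineConfig | None = None) -> BridgeTrialResult:
    """One planted-enrichment recovery trial on the demo landscape.

    The demo landscape plants a bridge cluster (pMKP) midway between the HSC
    and MK clusters with a 3x mutant multiplier.  The trial asks whether the
    most mutant-enriched fine node is dominated by bridge cells and whether
    its abstract-graph neighbors above the display threshold include both
    flanking coarse clusters.
    """
    cfg = config or PipelineConfig()
    spec = datagen.demo_landscape(n_reference_cells=n_reference_cells, seed=seed)
    ref, truth = datagen.generate_reference(spec)
    target = float(np.median(ref.totals()))
    norm = qc.normalize_total(ref, target)
    hvgs = mapping.select_hvgs(norm, ref.gene_ids,
                               n_hvgs=min(cfg.n_hvgs, ref.n_genes))
    model = mapping.fit_pca(norm, ref.gene_ids, hvgs, n_components=cfg.n_pcs,
                            seed=seed)
    emb = mapping.project(norm, ref.gene_ids, model)
    g = graph.build_knn_graph(emb, k=cfg.k_graph)
    fine = graph.louvain_partition(g, cfg.fine_resolution, seed=seed)
    fine_labels = np.array([f"F{l:02d}" for l in fine], dtype=object)
    query_embs = {}
    for geno, offset in [("WT", 10_000), ("MUT", 20_000)]:
        cm, _ = datagen.generate_query(spec, geno, n_query_cells,
                                       seed=offset + seed)
        query_embs[geno] = mapping.project(
            qc.normalize_total(cm, target), cm.gene_ids, model)
    votes = abundance.cast_votes(query_embs, emb, k=cfg.k_vote)
    d = abundance.abundance_difference(votes)
    na = abundance.node_abundance(d, fine_labels)
    top, _, _ = abundance.top_enriched_node(na)
    members = np.where(fine_labels == top)[0]
    top_majority = Counter(truth.coarse_label[members]).most_common(1)[0][0]
    ag = graph.paga_connectivity(g, fine_labels)
    flank_majorities = set()
    for nid in ag.neighbors_above(top, cfg.paga_edge_display_threshold):
        mem = ag.members[nid]
        flank_majorities.add(Counter(truth.coarse_label[mem]).most_common(1)[0][0])
    return BridgeTrialResult(
        top_is_bridge=(top_majority == "pMKP"),
        flanks_connected=("HSC" in flank_majorities and "MK" in flank_majorities),
        n_fine_clusters=len(set(fine_labels.tolist())),
        top_node=str(top),
    )


def doublet_auroc_trial(seed: int, n_cells: int = 800,
                        doublet_rate: float = 0.05) -> float:
    """AUROC of the doublet score for spiked doublets on a two-cluster mixture."""
    from sklearn.metrics import roc_auc_score

    clusters = [datagen.ClusterSpec("A", 0.5), datagen.ClusterSpec("B", 0.5)]
    spec = datagen.LandscapeSpec(
        n_genes=500, n_mito_genes=20, coarse_clusters=clusters,
        fine_per_coarse=1, latent_dim=4, cluster_separation=8.0,
        nb_dispersion=0.2, library_size_mean=2000,
        n_reference_cells=n_cells, seed=seed,
    )
    cm, truth = datagen.generate_reference(spec)
    cm, truth = datagen.spike_artifacts(cm, truth, doublet_rate, 0.0, seed=seed)
    synth = qc.simulate_doublets(cm, seed=seed)
    scores = qc.doublet_scores(cm, synth, seed=seed)
    return float(roc_auc_score(truth.is_doublet, scores.scores))


def de_recovery_trial(seed: int, n_per_genotype: int = 1000,
                      n_genes: int = 300, n_de: int = 20,
                      config: PipelineConfig | None = None):
    """Planted-DE recovery: returns (sensitivity on up-planted genes,
    false-positive rate on null genes, direction-consistency flag).

    Plants |log2FC| = 1 on well-expressed genes of a two-cluster landscape
    (half up, half down in the mutant) and tests the target cluster at about
    ``n_per_genotype``/2 cells per genotype.
    """
    cfg = config or PipelineConfig()

    def base(de_genes):
        clusters = [datagen.ClusterSpec("HSC", 0.5, de_genes=de_genes),
                    datagen.ClusterSpec("B", 0.5)]
        return datagen.LandscapeSpec(
            n_genes=n_genes, n_mito_genes=10, coarse_clusters=clusters,
            fine_per_coarse=1, latent_dim=4, cluster_separation=6.0,
            nb_dispersion=0.25, library_size_mean=2000, seed=seed,
        )

    idx = datagen.expressed_gene_indices(base([]), n_de)
    de_genes = [(g, 1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(idx)]
    spec = base(de_genes)
    wt, twt = datagen.generate_query(spec, "WT", n_per_genotype, seed=seed + 10_000)
    mut, tmut = datagen.generate_query(spec, "MUT", n_per_genotype, seed=seed + 20_000)
    target = 2000.0
    pooled = sp.vstack([
        qc.normalize_total(wt, target), qc.normalize_total(mut, target)
    ]).tocsr()
    genotype = np.array(["WT"] * wt.n_cells + ["MUT"] * mut.n_cells, dtype=object)
    labels = np.concatenate([twt.coarse_label, tmut.coarse_label])
    members = np.where(labels == "HSC")[0]
    table = de.de_table(pooled, wt.gene_ids, genotype, members, cfg)
    flag = table["is_de"].to_numpy()
    up = [g for g, l in de_genes if l > 0]
    planted = {g for g, _ in de_genes}
    sens = float(np.mean([flag[g] for g in up]))
    null_genes = [i for i in range(n_genes) if i not in planted]
    fpr = float(np.mean([flag[i] for i in null_genes]))
    direction_ok = all(table["log2fc"][g] > 0 for g in up if flag[g])
    return sens, fpr, direction_ok


def null_calibration_trial(seed: int, n_reference_cells: int = 1200,
                           n_query_cells: int = 600,
                           n_permutations: int = 200):
    """One null-configuration trial: all multipliers 1.

    Returns ``(n_exceeding, n_nodes)`` — how many coarse-cluster nodes have
    |mean d| above the permutation-null 95th percentile.
    """
    names = ["A", "B", "C", "D", "E", "F"]
    clusters = [datagen.ClusterSpec(n, 1 / 6) for n in names]
    spec = datagen.LandscapeSpec(
        n_genes=400, n_mito_genes=15, coarse_clusters=clusters,
        fine_per_coarse=3, latent_dim=6, cluster_separation=5.0,
        nb_dispersion=0.25, library_size_mean=2000,
        n_reference_cells=n_reference_cells, seed=seed,
    )
    ref, truth = datagen.generate_reference(spec)
    target = 2000.0
    norm = qc.normalize_total(ref, target)
    hvgs = mapping.select_hvgs(norm, ref.gene_ids, n_hvgs=300)
    model = mapping.fit_pca(norm, ref.gene_ids, hvgs, n_components=30, seed=seed)
    emb = mapping.project(norm, ref.gene_ids, model)
    g = graph.build_knn_graph(emb, k=7)
    fine = graph.louvain_partition(g, 3.0, seed=seed)
    fine_labels = np.array([f"F{l:02d}" for l in fine], dtype=object)
    query_embs = {}
    for geno, offset in [("WT", 10_000), ("MUT", 20_000)]:
        cm, _ = datagen.generate_query(spec, geno, n_query_cells, seed=offset + seed)
        query_embs[geno] = mapping.project(qc.normalize_total(cm, target),
                                           cm.gene_ids, model)
    node_ids, obs, q95 = abundance.node_permutation_null(
        query_embs, emb, fine_labels, k=15, n_permutations=n_permutations,
        seed=seed)
    return int((np.abs(obs) > q95).sum()), len(node_ids)


def qc_contract_counts():
    """Constructed-fixture QC check; returns measured vs expected counts.

    Builds matrices where rule outcomes are computable by hand: per-gate
    doublet removal fractions on 1000 cells, a >10% mito cell, a 499-gene
    cell next to a 500-gene cell, and a gross total-UMI outlier.
    """
    from .containers import CountMatrix

    out = {}
    rng = np.random.default_rng(0)
    for gate, frac, expected in [("LSK", 0.01, 10), ("LK", 0.045, 45)]:
        X = sp.csr_matrix(rng.integers(1, 5, size=(1000, 10)))
        cm = CountMatrix(X, [f"B{i:04d}" for i in range(1000)],
                         [f"g{j}" for j in range(10)], np.zeros(10, bool),
                         np.array(["S"] * 1000, object),
                         np.array([gate] * 1000, object))
        scores = qc.DoubletScores(rng.random(1000), 1000, 30, 20)
        keep = qc.remove_top_doublets(scores, cm, {gate: frac})
        out[f"doublet_removed_{gate.lower()}_per_1000"] = int((~keep).sum())

    cfg = PipelineConfig(min_genes=1, umi_sd_bound=100)
    X = np.full((20, 10), 5)
    X[3, 0] = 8  # cell 3: 8/53 = 15.1% mitochondrial
    cm = CountMatrix(sp.csr_matrix(X), [f"B{i}" for i in range(20)],
                     [f"g{j}" for j in range(10)],
                     np.eye(1, 10, 0, dtype=bool).ravel(),
                     np.array(["S"] * 20, object), np.array(["LSK"] * 20, object))
    _, report = qc.qc_filter(cm, cfg)
    out["mito_rule_removed"] = int(report.table["n_removed_mito"].sum())

    X = np.zeros((3, 600), dtype=int)
    X[0, :500] = 1
    X[1, :499] = 1
    X[2, :] = 1
    cm = CountMatrix(sp.csr_matrix(X), ["a", "b", "c"],
                     [f"g{j}" for j in range(600)], np.zeros(600, bool),
                     np.array(["S"] * 3, object), np.array(["LSK"] * 3, object))
    _, report = qc.qc_filter(cm, PipelineConfig(mito_fraction_max=0.99,
                                                umi_sd_bound=100))
    out["min_gene_rule_removed"] = int(report.table["n_removed_genes"].sum())

    X = np.full((101, 10), 100)
    X[100] = 100_000
    cm = CountMatrix(sp.csr_matrix(X), [f"B{i}" for i in range(101)],
                     [f"g{j}" for j in range(10)], np.zeros(10, bool),
                     np.array(["S"] * 101, object), np.array(["LSK"] * 101, object))
    _, report = qc.qc_filter(cm, PipelineConfig(min_genes=1, mito_fraction_max=0.99))
    out["umi_rule_removed"] = int(report.table["n_removed_umi_outlier"].sum())
    return out


# printed summary statistics from the depletion and clone experiments:
# (label, control (mean, sd, n), condition (mean, sd, n))
PRINTED_SUMMARIES = {
    "pmkp_frequency": (("WT", 0.00029, 0.00008, 3), ("HOM", 0.0025, 0.0008, 3)),
    "depletion_eslam": (("Cre-", 17.1, 10.8, 8), ("Cre+", 4.3, 2.0, 10)),
    "depletion_lthsc": (("Cre-", 15.0, 12.0, 8), ("Cre+", 3.6, 1.7, 10)),
    "depletion_mkp": (("Cre-", 44.2, 26.4, 8), ("Cre+", 21.4, 6.1, 10)),
    "depletion_mpp2": (("Cre-", 25.1, 29.1, 4), ("Cre+", 13.3, 3.6, 6)),
    "depletion_premege": (("Cre-", 90.0, 62.9, 4), ("Cre+", 73.9, 29.6, 6)),
    "pmkp_output_fraction": (("WT", 0.062, 0.015, 3), ("HOM", 0.193, 0.036, 3)),
}


def printed_statistics() -> dict:
    """Welch p-values recomputed from the published summary statistics, plus
    the depletion percentages for HSC (ESLAM), pMKP and MkP populations."""
    from .clones import SummaryStats, percent_depletion, welch_t_from_summary

    out = {}
    for key, (a, b) in PRINTED_SUMMARIES.items():
        sa = SummaryStats(a[0], a[1], a[2], a[3])
        sb = SummaryStats(b[0], b[1], b[2], b[3])
        _, _, p = welch_t_from_summary(sa, sb)
        out[f"welch_p_{key}"] = p
    out["percent_depletion_hsc"] = percent_depletion(17.1, 4.3)
    out["percent_depletion_pmkp"] = percent_depletion(13.0, 4.1)
    out["percent_depletion_mkp"] = percent_depletion(44.2, 21.4)
    return out
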