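"""End-to-end orchestration of the single-cell analysis.

Stage order mirrors the experimental analysis: per-sample QC (doublet
scoring/removal, hard filters), joint total-count normalization, reference
HVG selection and PCA, query projection, 15-NN label transfer, the k = 7
reference graph with coarse and fine Louvain partitions, graph abstraction,
kNN-vote differential abundance, and per-cluster differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import abundance, de, graph, mapping, qc
from .config import PipelineConfig
from .containers import CountMatrix

log = logging.getLogger("mklandscape")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_reports: dict = field(default_factory=dict)
    normalization_target: float = 0.0
    pca_model: object = None
    ref_embedding: np.ndarray = None
    query_embeddings: dict = field(default_factory=dict)
    assignments: dict = field(default_factory=dict)     # sample -> ClusterAssignment
    ref_coarse_labels: np.ndarray = None
    ref_fine_labels: np.ndarray = None
    neighbor_graph: object = None
    abstract_graph: object = None
    votes: object = None
    node_abundance: object = None
    top_node: tuple = None
    de_tables: dict = field(default_factory=dict)       # cluster -> DataFrame
    kept_ref: np.ndarray = None
    kept_query: dict = field(default_factory=dict)


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, reference: CountMatrix,
                 queries: dict, wildtype: str = "WT", mutant: str = "MUT",
                 do_qc: bool = True, do_de: bool = True) -> PipelineResult:
    """Run the full analysis; ``queries`` maps sample name -> CountMatrix.

    Deterministic given ``config.seed``.  Raises with the failing stage name
    on any stage error.
    """
    if len(queries) < 2:
        raise ValueError("need the reference plus at least two query samples")
    res = PipelineResult(config=config)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_qc = int(rng_seeds[0].generate_state(1)[0] % (2 ** 31))
    seed_pca = int(rng_seeds[1].generate_state(1)[0] % (2 ** 31))
    seed_cluster = int(rng_seeds[2].generate_state(1)[0] % (2 ** 31))

    stage = "qc"
    try:
        if do_qc:
            filt_queries = {}
            for name, cm in queries.items():
                filtered, report, _, kept = qc.run_qc(cm, config, seed=seed_qc)
                res.qc_reports[name] = report
                res.kept_query[name] = kept
                filt_queries[name] = filtered
                log.info("qc[%s]: %d -> %d cells", name, cm.n_cells,
                         filtered.n_cells)
            queries = filt_queries

        stage = "normalization"
        totals = np.concatenate(
            [reference.totals()] + [q.totals() for q in queries.values()]
        )
        target = (
            float(np.median(totals))
            if config.normalization_target is None
            else float(config.normalization_target)
        )
        res.normalization_target = target
        ref_norm = qc.normalize_total(reference, target)
        query_norm = {n: qc.normalize_total(q, target) for n, q in queries.items()}

        stage = "embedding"
        n_hvgs = min(config.n_hvgs, reference.n_genes)
        hvgs = mapping.select_hvgs(ref_norm, reference.gene_ids, n_hvgs=n_hvgs)
        model = mapping.fit_pca(
            ref_norm, reference.gene_ids, hvgs,
            n_components=min(config.n_pcs, len(hvgs), reference.n_cells - 1),
            scale_unit_variance=config.scale_unit_variance,
            clip=config.scale_clip, seed=seed_pca,
        )
        res.pca_model = model
        ref_emb = mapping.project(ref_norm, reference.gene_ids, model)
        res.ref_embedding = ref_emb
        res.query_embeddings = {
            n: mapping.project(q, queries[n].gene_ids, model)
            for n, q in query_norm.items()
        }

        stage = "clustering"
        g = graph.build_knn_graph(ref_emb, k=config.k_graph)
        res.neighbor_graph = g
        res.ref_coarse_labels = louvain_names(
            graph.louvain_partition(g, config.coarse_resolution, seed_cluster), "C"
        )
        res.ref_fine_labels = louvain_names(
            graph.louvain_partition(g, config.fine_resolution, seed_cluster), "F"
        )
        log.info("clustering: %d coarse / %d fine clusters",
                 len(set(res.ref_coarse_labels)), len(set(res.ref_fine_labels)))

        stage = "mapping"
        for name, emb in res.query_embeddings.items():
            res.assignments[name] = mapping.assign_clusters_knn(
                emb, ref_emb, res.ref_coarse_labels, k=config.k_map
            )

        stage = "abstraction"
        ag = graph.paga_connectivity(g, res.ref_fine_labels)
        ag.layout = graph.force_layout(
            len(ag.node_ids),
            [(i, j) for i, j, _ in ag.edges_above(config.paga_edge_display_threshold)],
            weights=[w for _, _, w in
                     ag.edges_above(config.paga_edge_display_threshold)],
            seed=seed_cluster,
        )
        res.abstract_graph = ag

        stage = "differential abundance"
        res.votes = abundance.cast_votes(
            res.query_embeddings, ref_emb, k=config.k_vote,
            scheme=config.vote_scheme,
        )
        d = abundance.abundance_difference(res.votes, mutant=mutant,
                                           wildtype=wildtype)
        res.node_abundance = abundance.node_abundance(d, res.ref_fine_labels)
        res.top_node = abundance.top_enriched_node(res.node_abundance)
        ag.node_values["mean_d"] = res.node_abundance.mean_d
        log.info("differential abundance: top node %s (mean d = %.3g)",
                 res.top_node[0], res.top_node[1])

        stage = "differential expression"
        if do_de:
            # pool query cells; test WT vs MUT within each mapped coarse cluster
            all_names = list(queries)
            pooled_norm = None
            import scipy.sparse as sp

            pooled_norm = sp.vstack([query_norm[n] for n in all_names]).tocsr()
            genotype = np.concatenate(
                [[("MUT" if n == mutant else "WT")] * queries[n].n_cells
                 for n in all_names]
            )
            labels = np.concatenate(
                [res.assignments[n].labels for n in all_names]
            )
            for cl in sorted(set(labels.tolist())):
                members = np.where(labels == cl)[0]
                geno = genotype[members]
                if (geno == "WT").sum() < 2 or (geno == "MUT").sum() < 2:
                    log.info("de[%s]: skipped (insufficient cells)", cl)
                    continue
                res.de_tables[cl] = de.de_table(
                    pooled_norm, reference.gene_ids, genotype, members,
                    config, cluster_name=cl,
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return res


def louvain_names(labels: np.ndarray, prefix: str) -> np.ndarray:
    return np.array([f"{prefix}{l:02d}" for l in labels], dtype=object)
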