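"""Per-cluster differential expression between genotypes.

Each gene is tested with a two-sided Wilcoxon rank-sum test (exact enumeration
when both groups have <= 10 cells, tie-corrected normal approximation
otherwise), p-values are Benjamini-Hochberg adjusted, and genes are gated as
differentially expressed when adjusted p < 0.05 and fold change > 1.5, with a
separate pathway-analysis export gate (adjusted p < 0.01, |log2FC| > 0.3785,
i.e. fold change beyond ~1.3 either way).  Fold change is computed on
arithmetic means of total-count-normalized expression with a small
pseudocount, mutant over wild type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

__all__ = [
    "wilcoxon_de",
    "exact_ranksum_p",
    "bh_adjust",
    "fold_change",
    "de_table",
    "deg_filter",
]

_EXACT_MAX = 10  # exact enumeration when both groups are at most this size


def exact_ranksum_p(x, y) -> tuple:
    """Exact two-sided rank-sum p over all equally likely group assignments.

    Handles ties via midranks.  Returns ``(U_x, p)`` where U_x is the
    Mann-Whitney U of the first sample.  The permutation distribution of the
    rank sum is computed by dynamic programming over (doubled, hence integer)
    midranks, which is exact and equivalent to full enumeration of the
    C(n+m, n) assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    r2 = np.round(ranks * 2).astype(int)  # midranks doubled -> integers
    s_max = int(r2.sum())
    # dp[k, s] = number of size-k subsets with doubled-rank-sum s
    dp = np.zeros((n + 1, s_max + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : s_max + 1 - r]
    counts = dp[n]
    s_vals = np.arange(s_max + 1)
    u_vals = s_vals / 2.0 - n * (n + 1) / 2.0
    mu = n * m / 2.0
    dev_obs = abs(u_obs - mu)
    extreme = counts[np.abs(u_vals - mu) >= dev_obs - 1e-9].sum()
    return u_obs, float(extreme / counts.sum())


def wilcoxon_de(norm_X, group_a_idx, group_b_idx):
    """Per-gene two-sided rank-sum test, group b (mutant) vs group a (WT).

    Returns ``(U_b, p)`` arrays over genes.  Exact enumeration when both
    groups have at most 10 cells; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    group_a_idx = np.asarray(group_a_idx)
    group_b_idx = np.asarray(group_b_idx)
    if len(group_a_idx) < 2 or len(group_b_idx) < 2:
        raise ValueError("need at least 2 cells per genotype")
    Xa = norm_X[group_a_idx]
    Xb = norm_X[group_b_idx]
    if sp.issparse(Xa):
        Xa, Xb = Xa.toarray(), Xb.toarray()
    n_genes = Xa.shape[1]
    if len(group_a_idx) <= _EXACT_MAX and len(group_b_idx) <= _EXACT_MAX:
        stat = np.empty(n_genes)
        p = np.empty(n_genes)
        for g in range(n_genes):
            u, pv = exact_ranksum_p(Xb[:, g], Xa[:, g])
            stat[g], p[g] = u, pv
        return stat, p
    res = stats.mannwhitneyu(Xb, Xa, axis=0, alternative="two-sided",
                             method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # a gene constant across both groups carries no signal
    const = (Xa.min(axis=0) == Xa.max(axis=0)) & \
            (Xb.min(axis=0) == Xb.max(axis=0)) & \
            (Xa.min(axis=0) == Xb.min(axis=0))
    p[const] = 1.0
    return np.asarray(res.statistic, dtype=float), p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("non-finite p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_mut, mean_wt, pseudocount: float = 0.01):
    """(FC, log2FC) with FC = (mean_mut + eps) / (mean_wt + eps)."""
    mean_mut = np.asarray(mean_mut, dtype=float)
    mean_wt = np.asarray(mean_wt, dtype=float)
    if (mean_mut < 0).any() or (mean_wt < 0).any():
        raise ValueError("means must be nonnegative")
    fc = (mean_mut + pseudocount) / (mean_wt + pseudocount)
    return fc, np.log2(fc)


def de_table(norm_X, gene_ids, genotype, cluster_members,
             config: PipelineConfig | None = None,
             cluster_name: str = "cluster") -> pd.DataFrame:
    """Full DE table for the cells of one cluster, WT vs MUT.

    ``genotype`` is a per-cell label array ("WT"/"MUT"); ``cluster_members``
    an index array into the rows of ``norm_X``.
    """
    config = config or PipelineConfig()
    genotype = np.asarray(genotype, dtype=object)
    members = np.asarray(cluster_members)
    sub_geno = genotype[members]
    idx_wt = members[sub_geno == "WT"]
    idx_mut = members[sub_geno == "MUT"]
    if len(idx_wt) == 0 or len(idx_mut) == 0:
        raise ValueError(
            f"cluster {cluster_name!r} contains only one genotype; cannot test"
        )
    stat, p = wilcoxon_de(norm_X, idx_wt, idx_mut)
    Xw = norm_X[idx_wt]
    Xm = norm_X[idx_mut]
    mean_wt = np.asarray(Xw.mean(axis=0)).ravel()
    mean_mut = np.asarray(Xm.mean(axis=0)).ravel()
    fc, l2fc = fold_change(mean_mut, mean_wt, config.fc_pseudocount)
    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object),
            "statistic": stat,
            "p": p,
            "adj_p": bh_adjust(p),
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "fc": fc,
            "log2fc": l2fc,
        }
    )
    return deg_filter(table, config)


def deg_filter(table: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Set the DE and pathway-export flags on a DE table."""
    config = config or PipelineConfig()
    fc_gate = table["fc"] > config.de_fc_min
    if config.two_sided_fc:
        fc_gate = fc_gate | (table["fc"] < 1.0 / config.de_fc_min)
    table = table.copy()
    table["is_de"] = (table["adj_p"] < config.de_adj_p_max) & fc_gate
    table["ipa_export"] = (table["adj_p"] < config.ipa_adj_p_max) & (
        table["log2fc"].abs() > config.ipa_abs_log2fc_min
    )
    return table
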