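"""Pipeline configuration.

Every numeric constant used by the analysis is collected here so that a run is
fully described by one object: the QC thresholds (10% mitochondrial fraction,
500 detected genes, 3-SD total-UMI rule, per-gate doublet removal fractions),
the dimensionality/neighborhood sizes (50 PCs, 15-NN mapping and voting,
k = 7 landscape graph), the graph-abstraction display threshold (0.3) and the
differential-expression gates (BH-adjusted p < 0.05 with fold change > 1.5,
and the pathway-export filter adjusted p < 0.01 with |log2FC| > 0.3785).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # --- QC ---
    mito_fraction_max: float = 0.10
    min_genes: int = 500
    umi_sd_bound: float = 3.0
    umi_rule_log: bool = False      # compute the 3-SD rule on log totals
    umi_rule_pooled: bool = False   # pool samples/gates for the 3-SD rule
    doublet_removal_fraction: dict = field(
        default_factory=lambda: {"LSK": 0.01, "LK": 0.045}
    )
    doublet_n_pcs: int = 30
    doublet_k: int = 20
    # --- normalization / embedding ---
    normalization_target: float | None = None  # None -> median library size
    n_hvgs: int = 2000
    n_pcs: int = 50
    scale_unit_variance: bool = True
    scale_clip: float = 10.0
    # --- mapping / graph / abundance ---
    k_map: int = 15
    k_graph: int = 7
    k_vote: int = 15
    vote_scheme: str = "weighted"
    coarse_resolution: float = 1.0
    fine_resolution: float = 8.0
    paga_edge_display_threshold: float = 0.3
    # --- differential expression ---
    de_adj_p_max: float = 0.05
    de_fc_min: float = 1.5
    two_sided_fc: bool = False
    fc_pseudocount: float = 0.01
    ipa_adj_p_max: float = 0.01
    ipa_abs_log2fc_min: float = 0.3785
    # --- misc ---
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mito_fraction_max < 1.0:
            raise ValueError("mito_fraction_max must lie in (0, 1)")
        if self.min_genes < 0:
            raise ValueError("min_genes must be nonnegative")
        if self.umi_sd_bound <= 0:
            raise ValueError("umi_sd_bound must be positive")
        for gate, frac in self.doublet_removal_fraction.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(
                    f"doublet_removal_fraction[{gate!r}] = {frac} outside [0, 1)"
                )
        for name in ("n_pcs", "k_map", "k_graph", "k_vote", "n_hvgs",
                     "doublet_n_pcs", "doublet_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vote_scheme not in ("weighted", "integer"):
            raise ValueError("vote_scheme must be 'weighted' or 'integer'")
        if not 0.0 <= self.paga_edge_display_threshold <= 1.0:
            raise ValueError("paga_edge_display_threshold must lie in [0, 1]")
        for name in ("de_adj_p_max", "ipa_adj_p_max"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.de_fc_min <= 0 or self.fc_pseudocount < 0:
            raise ValueError("fold-change parameters out of domain")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path: str) -> PipelineConfig:
    """Load a configuration file; unknown keys raise, missing keys default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
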