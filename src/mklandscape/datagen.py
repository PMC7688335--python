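"""Synthetic hematopoietic-landscape generator with known ground truth.

Emulates droplet scRNAseq of a stem/progenitor landscape: a reference sample
drawn from ~13 coarse clusters (each split into a few fine subclusters, giving
a ~63-node fine partition) and wild-type / mutant query samples whose cluster
proportions are rescaled by per-cluster multipliers.  One cluster may be
declared a "bridge": its centroid is placed midway between two named flanking
clusters, emulating an intermediate population on a differentiation
trajectory (the megakaryocyte-biased intermediate enriched in the disease
model).

Generative model
----------------
Each fine cluster has a centroid in a latent space; cells scatter around it
with isotropic Gaussian noise (SD ``latent_noise_sd``), so
``cluster_separation`` is the centroid distance in units of within-cluster SD.
Gene means are ``softplus(W z + b)`` (positive by construction), rescaled per
cell to a log-normal library size, and counts are drawn negative-binomially
with variance ``mu + dispersion * mu**2``.  Mitochondrial genes have zero
latent loading (housekeeping-like) and a baseline scaled to a target share of
the library, so the mitochondrial QC rule has a stable null.  Planted effects
(abundance multipliers, per-cluster differentially expressed genes, spiked
doublets and low-quality cells) are recorded in a :class:`GroundTruth` aligned
one-to-one with the emitted cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "ClusterSpec",
    "LandscapeSpec",
    "GroundTruth",
    "generate_reference",
    "generate_query",
    "spike_artifacts",
    "demo_landscape",
    "write_ground_truth",
]


@dataclass
class ClusterSpec:
    """One coarse cluster: its reference share, genotype multipliers and
    planted DE genes (pairs of gene index and log2 fold change in the mutant)."""

    name: str
    reference_proportion: float
    wt_multiplier: float = 1.0
    mut_multiplier: float = 1.0
    de_genes: list = field(default_factory=list)
    # place this cluster's centroid midway between two named clusters
    bridge_between: tuple | None = None


@dataclass
class LandscapeSpec:
    n_genes: int
    n_mito_genes: int
    coarse_clusters: list
    fine_per_coarse: int = 5
    latent_dim: int = 12
    cluster_separation: float = 5.0
    nb_dispersion: float = 0.25
    library_size_mean: float = 2500.0
    library_size_sigma: float = 0.3
    latent_noise_sd: float = 1.0
    fine_spread_fraction: float = 0.3
    mito_fraction_target: float = 0.04
    gene_scale: float = 1.0
    n_reference_cells: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be smaller than n_genes")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be nonnegative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.fine_per_coarse < 1:
            raise ValueError("fine_per_coarse must be at least 1")
        props = np.array([c.reference_proportion for c in self.coarse_clusters])
        if (props < 0).any():
            raise ValueError("reference_proportion must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"coarse reference_proportions sum to {props.sum()}, expected 1"
            )
        names = [c.name for c in self.coarse_clusters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cluster names")
        n_free = sum(1 for c in self.coarse_clusters if c.bridge_between is None)
        if self.latent_dim < n_free:
            raise ValueError(
                f"latent_dim={self.latent_dim} too small for {n_free} non-bridge clusters"
            )
        for c in self.coarse_clusters:
            if c.wt_multiplier <= 0 or c.mut_multiplier <= 0:
                raise ValueError(f"cluster {c.name}: multipliers must be positive")
            idx = [g for g, _ in c.de_genes]
            if len(set(idx)) != len(idx):
                raise ValueError(f"cluster {c.name}: duplicate de_genes indices")
            if any(g < 0 or g >= self.n_genes for g in idx):
                raise ValueError(f"cluster {c.name}: de_genes index out of range")


@dataclass
class GroundTruth:
    """Planted truth aligned with the cells/genes of the emitted CountMatrix."""

    coarse_label: np.ndarray
    fine_label: np.ndarray
    is_doublet: np.ndarray
    is_low_quality: np.ndarray
    gene_is_mito: np.ndarray
    planted_lfc: dict  # cluster name -> {gene index: log2FC}


class _LandscapeModel:
    """Deterministic landscape parameters shared by reference and queries."""

    def __init__(self, spec: LandscapeSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d, g = spec.latent_dim, spec.n_genes
        mito = np.zeros(g, dtype=bool)
        mito[:spec.n_mito_genes] = True
        self.gene_is_mito = mito
        W = rng.normal(0.0, spec.gene_scale / np.sqrt(d), size=(g, d))
        W[mito] = 0.0  # mitochondrial genes are cluster-independent
        self.W = W
        b = rng.normal(0.0, 1.5, size=g)
        base = np.logaddexp(0.0, b)  # softplus baseline
        t = spec.mito_fraction_target
        if spec.n_mito_genes > 0 and t > 0:
            factor = (t / (1 - t)) * base[~mito].sum() / base[mito].sum()
            self.mito_boost = np.where(mito, factor, 1.0)
        else:
            self.mito_boost = np.ones(g)
        self.b = b
        # coarse centroids: non-bridge clusters on orthogonal axes
        sep = spec.cluster_separation * spec.latent_noise_sd
        centroids = {}
        axis = 0
        for c in spec.coarse_clusters:
            if c.bridge_between is None:
                v = np.zeros(d)
                v[axis] = sep
                centroids[c.name] = v
                axis += 1
        for c in spec.coarse_clusters:
            if c.bridge_between is not None:
                a, bname = c.bridge_between
                if a not in centroids or bname not in centroids:
                    raise ValueError(
                        f"cluster {c.name}: bridge_between references unknown cluster"
                    )
                centroids[c.name] = 0.5 * (centroids[a] + centroids[bname])
        self.coarse_centroids = centroids
        # fine centroids: small isotropic perturbations of the coarse centroid
        self.fine_centroids = {}
        self.fine_names = {}
        spread = spec.fine_spread_fraction * sep
        for c in spec.coarse_clusters:
            names, cents = [], []
            for j in range(spec.fine_per_coarse):
                u = rng.normal(size=d)
                u /= np.linalg.norm(u)
                names.append(f"{c.name}.{j}")
                cents.append(centroids[c.name] + spread * u)
            self.fine_names[c.name] = names
            self.fine_centroids[c.name] = np.array(cents)

    def sample_cells(self, n_cells, proportions, rng, genotype=None):
        spec = self.spec
        clusters = spec.coarse_clusters
        n_per = rng.multinomial(n_cells, proportions)
        coarse, fine, Z = [], [], []
        for c, n in zip(clusters, n_per):
            if n == 0:
                continue
            fidx = rng.integers(spec.fine_per_coarse, size=n)
            cents = self.fine_centroids[c.name][fidx]
            Z.append(cents + spec.latent_noise_sd * rng.standard_normal((n, spec.latent_dim)))
            coarse.extend([c.name] * n)
            fine.extend([self.fine_names[c.name][j] for j in fidx])
        Z = np.vstack(Z)
        coarse = np.array(coarse, dtype=object)
        fine = np.array(fine, dtype=object)
        mu = np.logaddexp(0.0, Z @ self.W.T + self.b)  # softplus, (cells x genes)
        mu *= self.mito_boost
        if genotype == "MUT":
            for c in clusters:
                if not c.de_genes:
                    continue
                mask = coarse == c.name
                for gidx, lfc in c.de_genes:
                    mu[mask, gidx] *= 2.0 ** lfc
        sigma = spec.library_size_sigma
        lib = spec.library_size_mean * np.exp(
            rng.normal(-0.5 * sigma ** 2, sigma, size=n_cells)
        )
        mu *= (lib / mu.sum(axis=1))[:, None]
        if spec.nb_dispersion > 0:
            shape = 1.0 / spec.nb_dispersion
            lam = rng.gamma(shape, mu * spec.nb_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(np.int32)
        return sp.csr_matrix(counts), coarse, fine


def _planted_lfc(spec: LandscapeSpec) -> dict:
    return {c.name: dict(c.de_genes) for c in spec.coarse_clusters if c.de_genes}


def _make_cm(X, coarse, model, sample, gate_rng, prefix):
    n = X.shape[0]
    barcodes = np.array([f"{prefix}-{i:06d}" for i in range(n)], dtype=object)
    gene_ids = np.array(
        [f"mt-gene{i}" if model.gene_is_mito[i] else f"gene{i}"
         for i in range(model.spec.n_genes)],
        dtype=object,
    )
    gate = np.where(gate_rng.random(n) < 0.5, "LSK", "LK").astype(object)
    return CountMatrix(
        X=X,
        barcodes=barcodes,
        gene_ids=gene_ids,
        gene_is_mito=model.gene_is_mito.copy(),
        sample=np.array([sample] * n, dtype=object),
        gate=gate,
    )


def generate_reference(spec: LandscapeSpec, n_cells: int | None = None,
                       seed: int | None = None):
    """Draw the reference landscape sample.

    Returns ``(CountMatrix, GroundTruth)``.  Deterministic given the spec and
    seed (defaults: ``spec.n_reference_cells`` cells, ``spec.seed`` stream).
    """
    model = _LandscapeModel(spec)
    n_cells = spec.n_reference_cells if n_cells is None else n_cells
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    props = np.array([c.reference_proportion for c in spec.coarse_clusters])
    X, coarse, fine = model.sample_cells(n_cells, props, rng)
    cm = _make_cm(X, coarse, model, "REF", rng, "REF")
    truth = GroundTruth(
        coarse_label=coarse,
        fine_label=fine,
        is_doublet=np.zeros(n_cells, dtype=bool),
        is_low_quality=np.zeros(n_cells, dtype=bool),
        gene_is_mito=model.gene_is_mito.copy(),
        planted_lfc=_planted_lfc(spec),
    )
    return cm, truth


def generate_query(spec: LandscapeSpec, genotype: str, n_cells: int, seed: int):
    """Draw a query sample with genotype-specific cluster proportions.

    ``genotype`` selects ``wt_multiplier`` (``"WT"``) or ``mut_multiplier``
    (``"MUT"``); proportions are ``reference_proportion * multiplier``
    renormalized.  Planted DE genes are scaled by ``2**log2FC`` in mutant cells
    of their target cluster.
    """
    if genotype not in ("WT", "MUT"):
        raise ValueError(f"genotype must be 'WT' or 'MUT', got {genotype!r}")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    model = _LandscapeModel(spec)
    rng = np.random.default_rng(seed)
    mult = np.array(
        [c.wt_multiplier if genotype == "WT" else c.mut_multiplier
         for c in spec.coarse_clusters]
    )
    props = np.array([c.reference_proportion for c in spec.coarse_clusters]) * mult
    props /= props.sum()
    X, coarse, fine = model.sample_cells(n_cells, props, rng, genotype=genotype)
    cm = _make_cm(X, coarse, model, genotype, rng, genotype)
    truth = GroundTruth(
        coarse_label=coarse,
        fine_label=fine,
        is_doublet=np.zeros(n_cells, dtype=bool),
        is_low_quality=np.zeros(n_cells, dtype=bool),
        gene_is_mito=model.gene_is_mito.copy(),
        planted_lfc=_planted_lfc(spec),
    )
    return cm, truth


def spike_artifacts(cm: CountMatrix, truth: GroundTruth, doublet_rate: float,
                    low_quality_rate: float, seed: int):
    """Append spiked doublets and low-quality cells with truth flags set.

    Doublets are element-wise sums of two distinct cells sampled uniformly
    (cross-cluster pairs not forced).  Low-quality cells are copies of real
    cells either with the mitochondrial share forced above 10% or with fewer
    than 500 detected genes.  Rates of zero return the inputs unchanged.
    """
    for name, rate in [("doublet_rate", doublet_rate),
                       ("low_quality_rate", low_quality_rate)]:
        if not 0.0 <= rate < 0.5:
            raise ValueError(f"{name} must lie in [0, 0.5)")
    if doublet_rate == 0 and low_quality_rate == 0:
        return cm, truth
    rng = np.random.default_rng(seed)
    n = cm.n_cells
    rows, coarse, fine, samples, gates, barcodes = [], [], [], [], [], []
    is_doublet, is_lowq = [], []

    n_doub = int(round(doublet_rate * n))
    for i in range(n_doub):
        a, b = rng.choice(n, size=2, replace=False)
        rows.append(cm.X[a] + cm.X[b])
        coarse.append(f"doublet:{truth.coarse_label[a]}+{truth.coarse_label[b]}")
        fine.append(f"doublet:{truth.fine_label[a]}+{truth.fine_label[b]}")
        samples.append(cm.sample[a])
        gates.append(cm.gate[a])
        # parent row indices recorded in the barcode for traceability
        barcodes.append(f"DBL-{i:05d}-{a}-{b}")
        is_doublet.append(True)
        is_lowq.append(False)

    n_low = int(round(low_quality_rate * n))
    mito_idx = np.where(cm.gene_is_mito)[0]
    for i in range(n_low):
        a = int(rng.integers(n))
        row = cm.X[a].toarray().ravel().astype(np.int64)
        if len(mito_idx) > 0 and rng.random() < 0.5:
            # force mito fraction into (0.15, 0.6)
            target = rng.uniform(0.15, 0.6)
            non_mito = row.sum() - row[mito_idx].sum()
            want_mito = int(np.ceil(target / (1 - target) * max(non_mito, 1)))
            row[mito_idx] = rng.multinomial(
                want_mito, np.full(len(mito_idx), 1.0 / len(mito_idx))
            )
        else:
            # force detected genes below 500 by zeroing all but a small subset
            detected = np.where(row > 0)[0]
            keep = rng.choice(detected, size=min(200, len(detected)), replace=False)
            mask = np.zeros_like(row, dtype=bool)
            mask[keep] = True
            row[~mask] = 0
        rows.append(sp.csr_matrix(row))
        coarse.append(f"lowq:{truth.coarse_label[a]}")
        fine.append(f"lowq:{truth.fine_label[a]}")
        samples.append(cm.sample[a])
        gates.append(cm.gate[a])
        barcodes.append(f"LOWQ-{i:05d}")
        is_doublet.append(False)
        is_lowq.append(True)

    X = sp.vstack([cm.X] + rows).tocsr()
    cm_out = CountMatrix(
        X=X,
        barcodes=np.concatenate([cm.barcodes, np.array(barcodes, dtype=object)]),
        gene_ids=cm.gene_ids,
        gene_is_mito=cm.gene_is_mito,
        sample=np.concatenate([cm.sample, np.array(samples, dtype=object)]),
        gate=np.concatenate([cm.gate, np.array(gates, dtype=object)]),
    )
    truth_out = GroundTruth(
        coarse_label=np.concatenate([truth.coarse_label, np.array(coarse, dtype=object)]),
        fine_label=np.concatenate([truth.fine_label, np.array(fine, dtype=object)]),
        is_doublet=np.concatenate([truth.is_doublet, np.array(is_doublet, dtype=bool)]),
        is_low_quality=np.concatenate([truth.is_low_quality, np.array(is_lowq, dtype=bool)]),
        gene_is_mito=truth.gene_is_mito,
        planted_lfc=truth.planted_lfc,
    )
    return cm_out, truth_out


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    pd.DataFrame(
        {
            "coarse_label": truth.coarse_label,
            "fine_label": truth.fine_label,
            "is_doublet": truth.is_doublet.astype(int),
            "is_low_quality": truth.is_low_quality.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def expressed_gene_indices(spec: LandscapeSpec, n: int,
                           exclude_mito: bool = True) -> list:
    """Indices of the ``n`` most strongly expressed (baseline) genes.

    Planted differential expression is only a meaningful study condition on
    genes whose baseline expression is detectable; this helper ranks genes by
    the softplus baseline of the landscape model (which depends only on the
    spec's seed and gene axis, not on any planted effects) and returns the
    top ``n`` indices, sorted.
    """
    model = _LandscapeModel(spec)
    baseline = np.logaddexp(0.0, model.b)
    if exclude_mito:
        baseline = np.where(model.gene_is_mito, -np.inf, baseline)
    return sorted(int(i) for i in np.argsort(baseline)[::-1][:n])


def demo_landscape(n_genes: int = 2000, n_reference_cells: int = 5000,
                   seed: int = 0, bridge_multiplier: float = 3.0) -> LandscapeSpec:
    """The packaged demo landscape: 13 coarse clusters including a bridge
    cluster (pMKP-like) midway between the HSC and MK clusters, with the
    bridge enriched 3x in the mutant and modest HSC/MK enrichment; 30
    well-expressed genes carry planted |log2FC| = 1 in the HSC cluster."""
    other = ["MPP", "MEP", "GMP", "Ery", "Neu", "Mono", "Ly", "Baso", "Eo", "DC"]

    def clusters(de):
        return [
            ClusterSpec("HSC", 0.10, mut_multiplier=1.5, de_genes=de),
            ClusterSpec("MK", 0.06, mut_multiplier=1.5),
            ClusterSpec("pMKP", 0.04, mut_multiplier=bridge_multiplier,
                        bridge_between=("HSC", "MK")),
        ] + [ClusterSpec(name, 0.08) for name in other]

    def make(de):
        return LandscapeSpec(
            n_genes=n_genes,
            n_mito_genes=50,
            coarse_clusters=clusters(de),
            fine_per_coarse=5,
            latent_dim=12,
            cluster_separation=5.0,
            nb_dispersion=0.25,
            library_size_mean=2500.0,
            n_reference_cells=n_reference_cells,
            seed=seed,
        )

    idx = expressed_gene_indices(make([]), 30)
    de = [(g, 1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(idx)]
    return make(de)
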