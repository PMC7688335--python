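import numpy as np
import pytest
import scipy.sparse as sp

from mklandscape import datagen
from mklandscape.containers import CountMatrix


def make_cm(X, gate="LSK", sample="S1", mito_cols=(), barcodes=None):
    """Small hand-built CountMatrix for unit tests."""
    X = np.asarray(X)
    n, g = X.shape
    is_mito = np.zeros(g, dtype=bool)
    is_mito[list(mito_cols)] = True
    gates = np.array([gate] * n, dtype=object) if isinstance(gate, str) else np.asarray(gate, dtype=object)
    samples = np.array([sample] * n, dtype=object) if isinstance(sample, str) else np.asarray(sample, dtype=object)
    return CountMatrix(
        X=sp.csr_matrix(X),
        barcodes=barcodes if barcodes is not None else [f"BC{i:04d}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        gene_is_mito=is_mito,
        sample=samples,
        gate=gates,
    )


@pytest.fixture
def two_cluster_spec():
    """Two well-separated clusters; the workhorse for QC/mapping tests."""
    def _make(seed=0, n_genes=500, separation=8.0, n_ref=800, dispersion=0.2):
        clusters = [datagen.ClusterSpec("A", 0.5), datagen.ClusterSpec("B", 0.5)]
        return datagen.LandscapeSpec(
            n_genes=n_genes, n_mito_genes=20, coarse_clusters=clusters,
            fine_per_coarse=1, latent_dim=4, cluster_separation=separation,
            nb_dispersion=dispersion, library_size_mean=2000,
            n_reference_cells=n_ref, seed=seed,
        )
    return _make


@pytest.fixture
def small_landscape_spec():
    """Six-cluster landscape used for null-calibration style tests."""
    def _make(seed=0, mut_multipliers=None):
        names = ["A", "B", "C", "D", "E", "F"]
        mult = mut_multipliers or {}
        clusters = [
            datagen.ClusterSpec(n, 1 / 6, mut_multiplier=mult.get(n, 1.0))
            for n in names
        ]
        return datagen.LandscapeSpec(
            n_genes=400, n_mito_genes=15, coarse_clusters=clusters,
            fine_per_coarse=3, latent_dim=6, cluster_separation=5.0,
            nb_dispersion=0.25, library_size_mean=2000,
            n_reference_cells=1200, seed=seed,
        )
    return _make
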