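"""Core in-memory containers and CellRanger-style triplet I/O.

The central object is :class:`CountMatrix`, a sparse cells x genes UMI count
matrix carrying cell barcodes, gene identifiers, a mitochondrial-gene flag and
per-cell sample / sorting-gate labels.  Matrices are stored cells x genes
internally and written genes x cells on disk, matching the CellRanger
Matrix Market triplet dialect (matrix.mtx + barcodes.tsv + features.tsv).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "FormatError", "read_counts", "write_counts"]


class FormatError(ValueError):
    """Raised when an on-disk triplet is internally inconsistent."""


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class CountMatrix:
    """Sparse UMI counts (cells x genes) with aligned cell/gene annotations.

    Parameters
    ----------
    X
        Nonnegative integer sparse matrix, one row per cell.
    barcodes
        Unique cell barcodes, length ``n_cells``.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    gene_is_mito
        Boolean flag per gene (mitochondrial genes drive one of the QC rules).
    sample, gate
        Per-cell sample name and sorting gate (e.g. ``"LSK"`` / ``"LK"``).
    """

    X: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_is_mito: np.ndarray
    sample: np.ndarray
    gate: np.ndarray = field(default=None)

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        if self.X.shape[0] == 0 or self.X.shape[1] == 0:
            raise ValueError("CountMatrix must contain at least one cell and one gene")
        if (self.X.data < 0).any():
            raise ValueError("negative entries in count matrix")
        self.barcodes = _as_str_array(self.barcodes)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.gene_is_mito = np.asarray(self.gene_is_mito, dtype=bool)
        self.sample = _as_str_array(self.sample)
        if self.gate is None:
            self.gate = _as_str_array(["NA"] * self.n_cells)
        else:
            self.gate = _as_str_array(self.gate)
        n, g = self.X.shape
        for name, arr, want in [
            ("barcodes", self.barcodes, n),
            ("sample", self.sample, n),
            ("gate", self.gate, n),
            ("gene_ids", self.gene_ids, g),
            ("gene_is_mito", self.gene_is_mito, g),
        ]:
            if len(arr) != want:
                raise ValueError(f"{name} has length {len(arr)}, expected {want}")
        for name, arr in [("barcodes", self.barcodes), ("gene_ids", self.gene_ids)]:
            uniq, counts = np.unique(arr, return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1][:5].tolist()
                raise ValueError(f"duplicate {name}: {dup}")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def totals(self) -> np.ndarray:
        """Per-cell total UMI count."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.diff(self.X.indptr)

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of UMIs mapping to mitochondrial genes."""
        tot = self.totals().astype(float)
        mito = np.asarray(self.X[:, self.gene_is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1e-300), 0.0)
        return frac

    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return replace(
            self,
            X=self.X[index],
            barcodes=self.barcodes[index],
            sample=self.sample[index],
            gate=self.gate[index],
        )

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return replace(
            self,
            X=self.X[:, index].tocsr(),
            gene_ids=self.gene_ids[index],
            gene_is_mito=self.gene_is_mito[index],
        )

    def concat_cells(self, other: "CountMatrix") -> "CountMatrix":
        if not np.array_equal(self.gene_ids, other.gene_ids):
            raise ValueError("gene axes differ; cannot concatenate cells")
        return CountMatrix(
            X=sp.vstack([self.X, other.X]).tocsr(),
            barcodes=np.concatenate([self.barcodes, other.barcodes]),
            gene_ids=self.gene_ids,
            gene_is_mito=self.gene_is_mito,
            sample=np.concatenate([self.sample, other.sample]),
            gate=np.concatenate([self.gate, other.gate]),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) for interop."""
        import anndata  # optional at runtime; standard container elsewhere

        obs = pd.DataFrame(
            {"sample": self.sample, "gate": self.gate},
            index=pd.Index(self.barcodes, name="barcode"),
        )
        var = pd.DataFrame(
            {"is_mito": self.gene_is_mito},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        return anndata.AnnData(X=self.X.copy(), obs=obs, var=var)


def write_counts(cm: CountMatrix, path: str) -> None:
    """Write a CellRanger-style triplet plus a cell metadata TSV.

    ``matrix.mtx`` holds genes x rows / cells x columns (CellRanger dialect),
    ``features.tsv`` one gene id per line with the mito flag, ``barcodes.tsv``
    one barcode per line, and ``metadata.tsv`` the per-cell sample/gate labels.
    """
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"), cm.X.T.tocoo(), field="integer"
    )
    pd.DataFrame(
        {"gene_id": cm.gene_ids, "is_mito": cm.gene_is_mito.astype(int)}
    ).to_csv(os.path.join(path, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(cm.barcodes).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"barcode": cm.barcodes, "sample": cm.sample, "gate": cm.gate}
    ).to_csv(os.path.join(path, "metadata.tsv"), sep="\t", index=False)


def read_counts(path: str) -> CountMatrix:
    """Read a triplet written by :func:`write_counts`.

    Raises
    ------
    FormatError
        On dimension mismatches between the matrix and the label files, on
        duplicate identifiers, or on an empty matrix.
    """
    mtx_path = os.path.join(path, "matrix.mtx")
    X = sp.csr_matrix(scipy.io.mmread(mtx_path).T)
    features = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str).to_numpy()
    gene_ids = features[0].astype(str).to_numpy()
    if features.shape[1] > 1:
        gene_is_mito = features[1].astype(int).to_numpy().astype(bool)
    else:
        gene_is_mito = np.array([g.lower().startswith("mt-") for g in gene_ids])
    if X.shape[0] == 0:
        raise FormatError(f"{mtx_path}: matrix contains no cells")
    if X.shape[1] != len(gene_ids):
        raise FormatError(
            f"features.tsv lists {len(gene_ids)} genes but matrix.mtx has "
            f"{X.shape[1]} gene rows"
        )
    if X.shape[0] != len(barcodes):
        raise FormatError(
            f"barcodes.tsv lists {len(barcodes)} cells but matrix.mtx has "
            f"{X.shape[0]} cell columns"
        )
    uniq, counts = np.unique(gene_ids, return_counts=True)
    if (counts > 1).any():
        raise FormatError(f"features.tsv: duplicate gene ids {uniq[counts > 1][:5].tolist()}")
    meta_path = os.path.join(path, "metadata.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        meta = meta.loc[barcodes]
        sample = meta["sample"].astype(str).to_numpy()
        gate = meta["gate"].astype(str).to_numpy()
    else:
        sample = np.array(["sample"] * len(barcodes), dtype=object)
        gate = None
    try:
        return CountMatrix(X, barcodes, gene_ids, gene_is_mito, sample, gate)
    except ValueError as exc:  # surface as a format problem with the path
        raise FormatError(f"{path}: {exc}") from exc
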