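"""QC filtering, normalization, variable-gene selection, PCA, and clustering.

Filtering uses strict inequalities on genes detected and total UMIs, the
convention of the published QC windows. Normalization is log1p of
median-depth-scaled counts (log-CPM with the median library size as the
scale factor) — a deliberately simple, documented stand-in for regression-
based normalizations; co-expression analyses never see normalized values,
only raw UMIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_formats import CountMatrix


@dataclass
class EmbeddingMatrix:
    """A linear embedding of cells: coords (cells x d) plus gene loadings."""

    coords: np.ndarray
    basis: np.ndarray  # genes x d
    d: int
    provenance: str = ""
    barcodes: list[str] | None = None
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


def filter_cells(cm: CountMatrix, min_genes: int = 200, max_genes: int = 4000,
                 max_counts: int = 10000) -> CountMatrix:
    """Keep cells with min_genes < n_genes_detected < max_genes and
    total_umis < max_counts (all strict)."""
    if min_genes >= max_genes:
        raise ValueError("min_genes must be < max_genes")
    stats = cm.cell_stats()
    keep = (
        (stats["n_genes_detected"] > min_genes)
        & (stats["n_genes_detected"] < max_genes)
        & (stats["total_umis"] < max_counts)
    ).to_numpy()
    if not keep.any():
        warnings.warn("all cells removed by QC filter")
    return cm.subset_cells(keep)


def normalize_log_cpm(cm: CountMatrix) -> np.ndarray:
    """log(1 + counts * S / depth) with S the median cell depth.

    Returns a dense genes x cells matrix. Invariant to uniform rescaling of
    all library sizes (S tracks the rescaling).
    """
    depth = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    if np.any(depth == 0):
        bad = [cm.barcodes[i] for i in np.flatnonzero(depth == 0)]
        raise ValueError(f"zero-depth cells: {bad[:5]}{'...' if len(bad) > 5 else ''}")
    s = float(np.median(depth))
    x = cm.counts.toarray().astype(float)
    return np.log1p(x * (s / depth)[None, :])


def select_variable_genes(norm: np.ndarray, n_top: int,
                          gene_ids: list[str] | None = None) -> np.ndarray:
    """Indices of the n_top genes with highest variance of normalized
    expression; ties broken by gene id (lexicographic), falling back to
    row index when ids are absent."""
    if n_top > norm.shape[0]:
        raise ValueError("n_top exceeds gene count")
    var = norm.var(axis=1)
    keys = gene_ids if gene_ids is not None else [str(i) for i in range(len(var))]
    order = sorted(range(len(var)), key=lambda i: (-var[i], keys[i]))
    return np.array(order[:n_top], dtype=int)


def embed_pca(norm: np.ndarray, n_pcs: int, barcodes: list[str] | None = None,
              provenance: str = "log-cpm-median") -> EmbeddingMatrix:
    """PCA of cells in normalized gene space via SVD of the centered matrix.

    Sign convention: each component's largest-magnitude gene loading is
    positive, making the embedding deterministic.
    """
    n_genes, n_cells = norm.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, cells)")
    x = norm.T - norm.mean(axis=1)[None, :]  # cells x genes, centered
    u, s_vals, vt = np.linalg.svd(x, full_matrices=False)
    basis = vt[:n_pcs].T  # genes x d
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(basis[:, j])))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
            u[:, j] = -u[:, j]
    coords = x @ basis
    explained = (s_vals[:n_pcs] ** 2) / max(n_cells - 1, 1)
    return EmbeddingMatrix(coords=coords, basis=basis, d=n_pcs,
                           provenance=provenance, barcodes=barcodes,
                           explained_variance=explained)


def cluster_cells(emb: EmbeddingMatrix, k_neighbors: int = 15,
                  resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a kNN graph in embedding space."""
    n = emb.coords.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n_cells")
    if np.allclose(emb.coords, emb.coords[0]):
        warnings.warn("degenerate embedding: all points identical; one cluster")
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.array(part.membership, dtype=int)
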