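"""Readers, writers, and core containers for the standard formats the pipeline touches.

Count matrices follow the 10x convention: genes as rows, cells as columns,
Matrix Market triplets on disk (1-based) with companion gene/barcode TSVs.
Gzipped files are handled transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A required file is missing or malformed."""


class IntegrityError(ValueError):
    """Files are individually readable but mutually inconsistent."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with species/time annotation.

    ``timepoint_hpf`` is either a scalar (all cells share one sampling time)
    or a per-cell array of hours post-fertilization.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    species: str = ""
    timepoint_hpf: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape[0] != len(self.gene_ids):
            raise IntegrityError(
                f"{self.counts.shape[0]} matrix rows but {len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.barcodes):
            raise IntegrityError(
                f"{self.counts.shape[1]} matrix columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IntegrityError("gene ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise IntegrityError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def timepoints(self) -> np.ndarray:
        """Per-cell hpf values (broadcast if scalar)."""
        t = np.asarray(self.timepoint_hpf, dtype=float)
        if t.ndim == 0:
            return np.full(self.n_cells, float(t))
        return t

    def cell_stats(self) -> pd.DataFrame:
        """Per-cell QC statistics: genes detected and total UMIs."""
        m = self.counts
        n_genes_detected = np.asarray((m > 0).sum(axis=0)).ravel()
        total_umis = np.asarray(m.sum(axis=0)).ravel()
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "species": self.species,
                "timepoint_hpf": self.timepoints(),
                "n_genes_detected": n_genes_detected.astype(int),
                "total_umis": total_umis.astype(int),
            }
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        t = self.timepoint_hpf
        if isinstance(t, np.ndarray):
            t = t[idx]
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            barcodes=[self.barcodes[i] for i in idx],
            species=self.species,
            timepoint_hpf=t,
        )

    def subset_genes(self, idx: Sequence[int]) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            barcodes=list(self.barcodes),
            species=self.species,
            timepoint_hpf=self.timepoint_hpf,
        )


def make_cell_table(matrices: Iterable[CountMatrix]) -> pd.DataFrame:
    """Cell annotation table (one row per cell) across a set of count matrices."""
    return pd.concat([cm.cell_stats() for cm in matrices], ignore_index=True)


@dataclass
class OrthologMap:
    """1:1 ortholog pairs between species A and B gene ids."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [p[0] for p in self.pairs]
        b_ids = [p[1] for p in self.pairs]
        dup_a = _duplicates(a_ids)
        dup_b = _duplicates(b_ids)
        if dup_a or dup_b:
            raise FormatError(
                f"ortholog table violates 1:1 constraint; duplicated ids: "
                f"A={sorted(dup_a)} B={sorted(dup_b)}"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


@dataclass
class PipelineConfig:
    """All tunable analysis parameters in one place.

    Defaults are the standard analysis settings: QC windows (strict
    inequalities, 200 < n_genes < 4,000 and total UMIs < 10,000 for
    derived-species data; the ancestral-species upper gene bound is 7,000),
    the unbalanced-OT parameters epsilon=0.05, lambda1=1, lambda2=50 with 20
    growth-learning iterations, fate-commitment threshold 0.7, and lineage
    trees with min 10 cells per cluster node and edge-weight cutoff 0.15.
    """

    min_genes: int = 200
    max_genes: int = 4000
    max_counts: int = 10000
    epsilon: float = 0.05
    lambda1: float = 1.0
    lambda2: float = 50.0
    growth_iters: int = 20
    fate_threshold: float = 0.7
    tree_min_cells: int = 10
    tree_edge_cutoff: float = 0.15
    n_pcs: int = 30
    k_neighbors: int = 15
    cluster_resolution: float = 1.0
    n_hvg: int = 2000
    emd_max_points: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for name in ("epsilon", "lambda1", "lambda2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.fate_threshold <= 1):
            raise ValueError("fate_threshold must be in (0, 1]")
        if not (0 <= self.tree_edge_cutoff <= 1):
            raise ValueError("tree_edge_cutoff must be in [0, 1]")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(
        f"none of {list(stems)} (optionally .gz) found in {directory}"
    )


def _check_mtx_nnz(mtx_path: Path) -> None:
    """Reject coordinate files whose declared nnz disagrees with the triplet count."""
    with _open_maybe_gzip(mtx_path) as fh:
        size_line = None
        n_triplets = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if size_line is None:
                size_line = line
                continue
            n_triplets += 1
    if size_line is None:
        raise FormatError(f"{mtx_path}: missing size header")
    parts = size_line.split()
    if len(parts) != 3:
        raise FormatError(f"{mtx_path}: malformed size line {size_line!r}")
    declared = int(parts[2])
    if declared != n_triplets:
        raise IntegrityError(
            f"{mtx_path}: header declares {declared} entries but file has "
            f"{n_triplets} triplet lines"
        )


def read_10x_mtx(directory: str | Path, species: str = "",
                 timepoint_hpf: float = 0.0) -> CountMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + genes/features + barcodes).

    Matrix Market indices are 1-based on disk, 0-based in memory. The declared
    nnz must agree with the number of data lines (enforced by the MM reader).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx_path = _find_file(directory, ["matrix.mtx"])
    genes_path = _find_file(directory, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_file(directory, ["barcodes.tsv"])

    _check_mtx_nnz(mtx_path)
    with _open_maybe_gzip(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed header / triplet count mismatch
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path} contains non-integer values")
    mat = mat.astype(np.int64)

    with _open_maybe_gzip(genes_path) as fh:
        gene_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gzip(barcodes_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]

    if mat.shape[0] != len(gene_ids):
        raise IntegrityError(
            f"matrix declares {mat.shape[0]} genes but {genes_path.name} "
            f"lists {len(gene_ids)}"
        )
    if mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix declares {mat.shape[1]} cells but {barcodes_path.name} "
            f"lists {len(barcodes)}"
        )
    return CountMatrix(mat, gene_ids, barcodes, species=species,
                       timepoint_hpf=timepoint_hpf)


def write_10x_mtx(cm: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as an (uncompressed) 10x triplet directory."""
    if cm.counts.nnz and not np.allclose(cm.counts.data, np.round(cm.counts.data)):
        raise ValueError("counts must be integers")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts.astype(np.int64))
    scipy.io.mmwrite(directory / "matrix.mtx", mat, field="integer")
    with open(directory / "genes.tsv", "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Read a 2-column TSV of 1:1 ortholog pairs; header auto-detected.

    A first row is treated as a header when it repeats in neither column of
    the remaining rows (heuristic: both fields look like column names, i.e.
    the file has >1 row and the first row's fields never recur as ids).
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        warnings.warn(f"empty ortholog table: {path}")
        return OrthologMap([])
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise FormatError(f"{path}: line {i + 1} has fewer than 2 columns")
    pairs = [(r[0], r[1]) for r in rows]
    header_words = ("gene", "ortholog", "species", "id_a", "id_b")
    head = pairs[0]
    if any(w in head[0].lower() or w in head[1].lower() for w in header_words):
        pairs = pairs[1:]
    return OrthologMap(pairs)


def write_ortholog_table(om: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in om.pairs:
            fh.write(f"{a}\t{b}\n")


# --- lineage graph JSON (d3.js-style nodes/links) ---------------------------


def write_lineage_graph(graph, path: str | Path) -> None:
    """Serialize a LineageGraph to d3-style JSON: nodes + weighted links."""
    payload = {
        "nodes": [
            {
                "id": n.node_id,
                "cluster": n.cluster,
                "timepoint": n.timepoint,
                "n_cells": n.n_cells,
            }
            for n in graph.nodes
        ],
        "links": [
            {
                "source": e.parent,
                "target": e.child,
                "weight": float(f"{e.weight:.8g}"),
            }
            for e in graph.edges
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_lineage_graph(path: str | Path):
    from .fate_views import LineageGraph, LineageNode, LineageEdge

    with open(path) as fh:
        payload = json.load(fh)
    nodes = [
        LineageNode(n["id"], n["cluster"], n["timepoint"], n["n_cells"])
        for n in payload["nodes"]
    ]
    edges = [
        LineageEdge(e["source"], e["target"], e["weight"])
        for e in payload["links"]
    ]
    return LineageGraph(nodes=nodes, edges=edges)
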