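"""Triangle-plot commitment views and lineage-tree construction.

A triangle plot places each cell inside an equilateral triangle according to
its barycentric fate coordinates (focal fate A at the top vertex, focal fate
B at the right, all remaining fates pooled at the bottom-left); a cell is
"committed" to a fate when that fate's probability reaches the threshold
(0.7 by default). Lineage trees connect cluster nodes at consecutive time
points by the mass-weighted fraction of descendants, with the printed
cluster-size (10 cells) and edge-weight (0.15) cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transport import FateMatrix, TransportMap

# equilateral triangle vertices: A top, B right, other at the origin
_V_A = np.array([0.5, np.sqrt(3.0) / 2.0])
_V_B = np.array([1.0, 0.0])
_V_OTHER = np.array([0.0, 0.0])


@dataclass
class TrianglePoint:
    barcode: str
    p_fate_A: float
    p_fate_B: float
    p_other: float
    committed_to: str  # "A", "B", "other", or "uncommitted"
    x: float
    y: float


@dataclass
class LineageNode:
    node_id: str
    cluster: str
    timepoint: float
    n_cells: int


@dataclass
class LineageEdge:
    parent: str
    child: str
    weight: float


@dataclass
class LineageGraph:
    nodes: list[LineageNode] = field(default_factory=list)
    edges: list[LineageEdge] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.parent, e.child) for e in self.edges}

    def node_map(self) -> dict[str, LineageNode]:
        return {n.node_id: n for n in self.nodes}


def triangle_projection(fates: FateMatrix, fate_A: str, fate_B: str,
                        threshold: float = 0.7) -> list[TrianglePoint]:
    """Barycentric projection of fate probabilities onto the triangle."""
    if fate_A == fate_B:
        raise ValueError("fate_A and fate_B must differ")
    for f in (fate_A, fate_B):
        if f not in fates.fate_names:
            raise ValueError(f"unknown fate {f!r}; have {fates.fate_names}")
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    p_a = fates.column(fate_A)
    p_b = fates.column(fate_B)
    others = [f for f in fates.fate_names if f not in (fate_A, fate_B)]
    p_o = (np.sum([fates.column(f) for f in others], axis=0)
           if others else np.zeros_like(p_a))
    barcodes = fates.barcodes or [str(i) for i in range(len(p_a))]
    out = []
    for i, bc in enumerate(barcodes):
        xy = p_a[i] * _V_A + p_b[i] * _V_B + p_o[i] * _V_OTHER
        if p_a[i] >= threshold:
            committed = "A"
        elif p_b[i] >= threshold:
            committed = "B"
        elif p_o[i] >= threshold:
            committed = "other"
        else:
            committed = "uncommitted"
        out.append(TrianglePoint(bc, float(p_a[i]), float(p_b[i]),
                                 float(p_o[i]), committed,
                                 float(xy[0]), float(xy[1])))
    return out


def build_lineage_graph(maps: list[TransportMap], clusters: pd.DataFrame,
                        min_cells: int = 10,
                        edge_cutoff: float = 0.15) -> LineageGraph:
    """Cluster-to-cluster descendant fractions from the solved couplings.

    weight(i -> j) = mass transported from cluster i to cluster j divided by
    all mass leaving cluster i (growth-adjusted gamma, not re-normalized
    Markov rows). Nodes with fewer than ``min_cells`` cells are removed
    before weights are computed (their cells drop out of the sums); edges
    below ``edge_cutoff`` are removed afterwards.

    ``clusters`` needs columns barcode, timepoint_hpf, cluster.
    """
    lut = clusters.set_index("barcode")["cluster"]
    sizes = clusters.groupby(["timepoint_hpf", "cluster"]).size()
    keep_nodes = {(t, c) for (t, c), n in sizes.items() if n >= min_cells}
    nodes: dict[str, LineageNode] = {}
    edges: list[LineageEdge] = []
    for tm in sorted(maps, key=lambda m: m.source_timepoint):
        if tm.source_barcodes is None or tm.target_barcodes is None:
            raise ValueError("transport maps must carry barcodes")
        t0, t1 = tm.source_timepoint, tm.target_timepoint
        src_cl = lut.reindex(tm.source_barcodes).to_numpy()
        tgt_cl = lut.reindex(tm.target_barcodes).to_numpy()
        src_keep = np.array([(t0, c) in keep_nodes for c in src_cl])
        tgt_keep = np.array([(t1, c) in keep_nodes for c in tgt_cl])
        gamma = tm.gamma[np.ix_(src_keep, tgt_keep)]
        src_cl = src_cl[src_keep]
        tgt_cl = tgt_cl[tgt_keep]
        if gamma.size == 0 or gamma.sum() == 0:
            warnings.warn(f"no surviving clusters for {t0} -> {t1}")
            continue
        for t, cls in ((t0, src_cl), (t1, tgt_cl)):
            for c in pd.unique(cls):
                nid = f"{c}@{t:g}"
                if nid not in nodes:
                    nodes[nid] = LineageNode(nid, str(c), float(t),
                                             int(sizes[(t, c)]))
        src_groups = {c: np.flatnonzero(src_cl == c) for c in pd.unique(src_cl)}
        tgt_groups = {c: np.flatnonzero(tgt_cl == c) for c in pd.unique(tgt_cl)}
        for ci, si in src_groups.items():
            total = gamma[si, :].sum()
            if total <= 0:
                continue
            for cj, sj in tgt_groups.items():
                w = gamma[np.ix_(si, sj)].sum() / total
                if w >= edge_cutoff:
                    edges.append(LineageEdge(f"{ci}@{t0:g}", f"{cj}@{t1:g}",
                                             float(w)))
    return LineageGraph(nodes=list(nodes.values()), edges=edges)


def descendant_fractions(tm: TransportMap, clusters: pd.DataFrame,
                         min_cells: int = 10) -> pd.DataFrame:
    """Pre-cutoff descendant fractions for one interval (rows sum to 1)."""
    g = build_lineage_graph([tm], clusters, min_cells=min_cells, edge_cutoff=0.0)
    return pd.DataFrame(
        [(e.parent, e.child, e.weight) for e in g.edges],
        columns=["parent", "child", "weight"],
    )


def map_clusters_to_lineages(clusters: pd.DataFrame,
                             truth_cells: pd.DataFrame) -> dict[str, str]:
    """Majority-lineage label for every (cluster, timepoint) node id."""
    merged = clusters.merge(truth_cells[["barcode", "lineage"]], on="barcode")
    out = {}
    for (t, c), grp in merged.groupby(["timepoint_hpf", "cluster"]):
        out[f"{c}@{t:g}"] = grp["lineage"].mode().iloc[0]
    return out


def graph_edge_f1(predicted: LineageGraph, truth: LineageGraph,
                  node_mapping: dict[str, str] | None = None) -> float:
    """F1 over edge sets, after mapping predicted cluster nodes to lineage
    labels (majority-lineage relabeling collapses duplicate edges)."""

    def relabel(graph: LineageGraph, mapping: dict[str, str] | None):
        edges = set()
        for e in graph.edges:
            pn = graph.node_map()
            if mapping is not None:
                p_lin = mapping.get(e.parent)
                c_lin = mapping.get(e.child)
                if p_lin is None or c_lin is None:
                    warnings.warn(f"unmappable edge {e.parent}->{e.child}")
                    edges.add((e.parent, e.child))  # counts as mismatch
                    continue
                pt = pn[e.parent].timepoint
                ct = pn[e.child].timepoint
                edges.add((f"{p_lin}@{pt:g}", f"{c_lin}@{ct:g}"))
            else:
                edges.add((e.parent, e.child))
        return edges

    pred = relabel(predicted, node_mapping)
    true = relabel(truth, None)
    if not pred and not true:
        return 1.0
    tp = len(pred & true)
    if tp == 0:
        return 0.0
    precision = tp / len(pred)
    recall = tp / len(true)
    return 2 * precision * recall / (precision + recall)
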