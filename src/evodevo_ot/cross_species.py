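"""Cross-species joint embedding and developmental time alignment.

The alignment follows the transport-based recipe: restrict both species to
1:1 orthologs, place all cells in a shared linear embedding, weight cells at
each (species, time point) by their fate probability toward a focal
lineage, and compute a time-point-by-time-point matrix of earth mover
distances between the two weighted clouds. For each species-A time point,
the species-B time point at minimal EMD is its developmental match; a
species that runs "late" shows matches above the slope-1 diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .io_formats import CountMatrix, OrthologMap
from .preprocess import EmbeddingMatrix
from .transport import FateMatrix


@dataclass
class AlignmentResult:
    """EMD matrix and best-pair matches for one cell lineage."""

    cell_lineage: str
    timepoints_A: list[float]
    timepoints_B: list[float]
    emd: np.ndarray  # |T_A| x |T_B|
    best_pairs: list[tuple[float, float]]  # (t_A, argmin-EMD t_B)
    missing_rows: list[float] = field(default_factory=list)
    missing_cols: list[float] = field(default_factory=list)

    def median_offset(self) -> float:
        """Median of s - t over best pairs: positive when B lags A."""
        return float(np.median([s - t for t, s in self.best_pairs]))

    def n_above_diagonal(self) -> int:
        """Count of best pairs with s > t (B later than A)."""
        return sum(1 for t, s in self.best_pairs if s > t)


def restrict_to_orthologs(cm_a: CountMatrix, cm_b: CountMatrix,
                          om: OrthologMap) -> tuple[CountMatrix, CountMatrix]:
    """Reduce both matrices to the 1:1 ortholog pairs, identically ordered."""
    idx_a_map = {g: i for i, g in enumerate(cm_a.gene_ids)}
    idx_b_map = {g: i for i, g in enumerate(cm_b.gene_ids)}
    rows_a, rows_b, dropped = [], [], []
    for ga, gb in om.pairs:
        ia = idx_a_map.get(ga)
        ib = idx_b_map.get(gb)
        if ia is None or ib is None:
            dropped.append((ga, gb))
            continue
        rows_a.append(ia)
        rows_b.append(ib)
    if dropped:
        warnings.warn(f"{len(dropped)} ortholog pairs absent from a matrix; dropped")
    if not rows_a:
        raise ValueError("no ortholog pairs shared between the two matrices")
    return cm_a.subset_genes(rows_a), cm_b.subset_genes(rows_b)


def _standardize_genes(norm: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance genes (rows); constant genes stay zero."""
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (norm - mu) / sd


def joint_embedding_cca(norm_a: np.ndarray, norm_b: np.ndarray,
                        k: int = 30) -> tuple[EmbeddingMatrix, EmbeddingMatrix]:
    """Shared embedding from the SVD of the cross-covariance through genes.

    With X_A, X_B the gene-standardized matrices (genes x cells), the top-k
    singular triplets (u_j, s_j, v_j) of K = X_A^T X_B define shared gene-
    space directions w_j ~ X_A u_j + X_B v_j (each normalized); cell
    coordinates are each species' standardized data projected on those
    directions. This is the diagonal-covariance simplification of CCA: both
    species land in one metric space without any anchor heuristics.
    Deterministic sign convention: the largest-magnitude gene loading of
    each direction is positive.
    """
    if norm_a.shape[0] != norm_b.shape[0]:
        raise ValueError("matrices must share the ortholog-restricted gene axis")
    n_genes = norm_a.shape[0]
    if k > n_genes:
        raise ValueError("k exceeds gene count")
    xa = _standardize_genes(np.asarray(norm_a, dtype=float))
    xb = _standardize_genes(np.asarray(norm_b, dtype=float))
    K = (xa.T @ xb) / max(n_genes - 1, 1)
    k_eff = min(k, min(K.shape))
    if k_eff < min(K.shape) - 1 and min(K.shape) > 20:
        u, s, vt = scipy.sparse.linalg.svds(K, k=k_eff)
        order = np.argsort(-s)
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u, s, vt = np.linalg.svd(K, full_matrices=False)
        u, s, vt = u[:, :k_eff], s[:k_eff], vt[:k_eff]
    v = vt.T
    w = xa @ u + xb @ v  # genes x k shared directions
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    w = w / norms[None, :]
    for j in range(k_eff):
        i = int(np.argmax(np.abs(w[:, j])))
        if w[i, j] < 0:
            w[:, j] = -w[:, j]
    coords_a = xa.T @ w
    coords_b = xb.T @ w
    emb_a = EmbeddingMatrix(coords=coords_a, basis=w.copy(), d=k_eff,
                            provenance="cross-covariance SVD (A)",
                            explained_variance=s.copy())
    emb_b = EmbeddingMatrix(coords=coords_b, basis=w.copy(), d=k_eff,
                            provenance="cross-covariance SVD (B)",
                            explained_variance=s.copy())
    return emb_a, emb_b


def emd(points_x: np.ndarray, weights_x: np.ndarray,
        points_y: np.ndarray, weights_y: np.ndarray,
        max_points: int = 2000, seed: int = 0) -> float:
    """Exact earth mover distance between two weighted point clouds.

    Solves the transportation linear program min <D, g> subject to the two
    marginal constraints (Euclidean ground metric, weights renormalized to
    1). Clouds larger than ``max_points`` are down-sampled with a fixed seed
    by weighted resampling; the EMD of the subsample stands in for the full
    cloud.
    """
    points_x = np.atleast_2d(np.asarray(points_x, dtype=float))
    points_y = np.atleast_2d(np.asarray(points_y, dtype=float))
    weights_x = np.asarray(weights_x, dtype=float)
    weights_y = np.asarray(weights_y, dtype=float)
    if points_x.shape[0] == 0 or points_y.shape[0] == 0:
        raise ValueError("empty point cloud")
    if weights_x.min() < 0 or weights_y.min() < 0:
        raise ValueError("weights must be nonnegative")
    if weights_x.sum() <= 0 or weights_y.sum() <= 0:
        raise ValueError("cloud has zero total weight")
    points_x, weights_x = _downsample(points_x, weights_x, max_points, seed)
    points_y, weights_y = _downsample(points_y, weights_y, max_points, seed + 1)
    a = weights_x / weights_x.sum()
    b = weights_y / weights_y.sum()
    D = cdist(points_x, points_y)
    n, m = D.shape
    # row constraints then column constraints (drop last, redundant)
    rows_i, cols_i, data = [], [], []
    for i in range(n):
        rows_i.extend([i] * m)
        cols_i.extend(range(i * m, (i + 1) * m))
        data.extend([1.0] * m)
    for j in range(m - 1):
        rows_i.extend([n + j] * n)
        cols_i.extend(range(j, n * m, m))
        data.extend([1.0] * n)
    A_eq = sp.csr_matrix((data, (rows_i, cols_i)), shape=(n + m - 1, n * m))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(D.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"EMD linear program failed: {res.message}")
    return float(res.fun)


def _downsample(points: np.ndarray, weights: np.ndarray, cap: int,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    if points.shape[0] <= cap:
        return points, weights
    rng = np.random.default_rng(seed)
    p = weights / weights.sum()
    idx = rng.choice(points.shape[0], size=cap, replace=True, p=p)
    uniq, counts = np.unique(idx, return_counts=True)
    return points[uniq], counts.astype(float)


def align_timecourses(coords_a: np.ndarray, times_a: np.ndarray,
                      coords_b: np.ndarray, times_b: np.ndarray,
                      fates_a: FateMatrix, fates_b: FateMatrix,
                      lineage_fate_map: dict[str, tuple[str, str]],
                      max_points: int = 2000, seed: int = 0,
                      min_total_weight: float = 1e-6) -> list[AlignmentResult]:
    """Per-lineage EMD alignment of the two developmental time courses.

    ``coords_*`` are cells x d joint-embedding coordinates, ``times_*`` the
    per-cell hpf labels; ``lineage_fate_map`` maps a lineage name to the
    (species A fate, species B fate) pair of homologous terminal fates. Fate
    matrices must cover the same cells, referenced to each species' own
    final time point.
    """
    tps_a = sorted(float(t) for t in set(np.asarray(times_a, dtype=float)))
    tps_b = sorted(float(t) for t in set(np.asarray(times_b, dtype=float)))
    results = []
    for lineage, (fate_a_name, fate_b_name) in lineage_fate_map.items():
        wa = fates_a.column(fate_a_name)
        wb = fates_b.column(fate_b_name)
        mat = np.full((len(tps_a), len(tps_b)), np.nan)
        missing_rows, missing_cols = [], []
        cloud_a, cloud_b = {}, {}
        for t in tps_a:
            m = np.asarray(times_a, dtype=float) == t
            if wa[m].sum() < min_total_weight:
                missing_rows.append(t)
            else:
                cloud_a[t] = (coords_a[m], wa[m])
        for s_tp in tps_b:
            m = np.asarray(times_b, dtype=float) == s_tp
            if wb[m].sum() < min_total_weight:
                missing_cols.append(s_tp)
            else:
                cloud_b[s_tp] = (coords_b[m], wb[m])
        for i, t in enumerate(tps_a):
            if t not in cloud_a:
                continue
            for j, s_tp in enumerate(tps_b):
                if s_tp not in cloud_b:
                    continue
                px, wx = cloud_a[t]
                py, wy = cloud_b[s_tp]
                mat[i, j] = emd(px, wx, py, wy, max_points=max_points,
                                seed=seed)
        best = []
        for i, t in enumerate(tps_a):
            row = mat[i]
            if np.all(np.isnan(row)):
                continue
            j = int(np.nanargmin(row))  # ties -> earliest B timepoint
            best.append((float(t), float(tps_b[j])))
        results.append(AlignmentResult(
            cell_lineage=lineage, timepoints_A=tps_a, timepoints_B=tps_b,
            emd=mat, best_pairs=best, missing_rows=missing_rows,
            missing_cols=missing_cols))
    return results
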