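"""Unbalanced entropic optimal transport between consecutive time points.

The trajectory model couples cells at time t to cells at time t+1 by
minimizing

    <C, g> - eps * H(g) + lambda1 * KL(g 1 | a) + lambda2 * KL(g^T 1 | b)

where H(g) = -sum g_ij (log g_ij - 1) and KL(x|y) = sum x log(x/y) - x + y.
The marginal penalties relax mass conservation: source cells may create or
destroy mass, which is how proliferation enters (a cell's source weight is
g_i^dt, its expected number of descendants over the interval). The solver is
the generalized Sinkhorn scaling

    u <- (a / K v)^(lambda1 / (lambda1 + eps)),
    v <- (b / K^T u)^(lambda2 / (lambda2 + eps)),   K = exp(-C / eps),

with g = diag(u) K diag(v). Growth rates are learned by alternating solves
with growth-informed source weights and updates from the realized row
marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EmbeddingMatrix


@dataclass
class TransportMap:
    """Nonnegative coupling between cells at consecutive time points."""

    gamma: np.ndarray
    epsilon: float
    lambda1: float
    lambda2: float
    source_timepoint: float
    target_timepoint: float
    source_barcodes: list[str] | None = None
    target_barcodes: list[str] | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(g)) or g.min() < 0:
            raise ValueError("transport map entries must be finite and >= 0")
        if g.sum() <= 0:
            raise ValueError("transport map has no mass")
        self.gamma = g

    def row_stochastic(self) -> tuple[np.ndarray, np.ndarray]:
        """Markov transition matrix (rows renormalized) and a zero-row flag."""
        rows = self.gamma.sum(axis=1)
        zero = rows <= 0
        safe = np.where(zero, 1.0, rows)
        return self.gamma / safe[:, None], zero


@dataclass
class GrowthModel:
    """Per-cell growth rates g (expected descendants per hour) by timepoint."""

    g: dict[float, np.ndarray]
    expected_totals: dict[float, float]


@dataclass
class FateMatrix:
    """Per-cell probabilities over terminal fates at a reference time point."""

    probs: np.ndarray
    fate_names: list[str]
    reference_timepoint: float
    barcodes: list[str] | None = None
    zero_mass: np.ndarray | None = None  # rows with no transported mass

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.min() < -1e-12 or p.max() > 1 + 1e-8:
            raise ValueError("fate probabilities outside [0, 1]")
        self.probs = p

    def column(self, fate: str) -> np.ndarray:
        return self.probs[:, self.fate_names.index(fate)]


def cost_matrix(x_t: np.ndarray, x_t1: np.ndarray) -> np.ndarray:
    """Squared Euclidean costs in embedding space, median-normalized.

    The division by the median nonzero entry makes epsilon scale-free
    across data sets.
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    x_t1 = np.atleast_2d(np.asarray(x_t1, dtype=float))
    if x_t.shape[0] == 0 or x_t1.shape[0] == 0:
        raise ValueError("empty embedding slice")
    d2 = ((x_t[:, None, :] - x_t1[None, :, :]) ** 2).sum(axis=2)
    nz = d2[d2 > 0]
    if nz.size:
        d2 = d2 / np.median(nz)
    return d2


def solve_unbalanced_ot(C: np.ndarray, a: np.ndarray, b: np.ndarray,
                        epsilon: float = 0.05, lambda1: float = 1.0,
                        lambda2: float = 50.0, max_iter: int = 5000,
                        tol: float = 1e-8, source_timepoint: float = 0.0,
                        target_timepoint: float = 1.0) -> TransportMap:
    """Generalized Sinkhorn scaling for KL-relaxed entropic transport."""
    C = np.asarray(C, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.min() < 0 or b.min() < 0 or a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("marginal weights must be nonnegative with positive sum")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix must be finite")
    K = np.exp(-C / epsilon)
    if not np.all(K.sum(axis=1) > 0) or not np.all(K.sum(axis=0) > 0):
        raise ValueError(
            "kernel exp(-C/epsilon) underflowed; rescale costs or raise epsilon"
        )
    p1 = lambda1 / (lambda1 + epsilon)
    p2 = lambda2 / (lambda2 + epsilon)
    u = np.ones_like(a)
    v = np.ones_like(b)
    tiny = 1e-300
    converged = False
    it = 0
    prev_row = None
    for it in range(1, max_iter + 1):
        u = (a / np.maximum(K @ v, tiny)) ** p1
        v = (b / np.maximum(K.T @ u, tiny)) ** p2
        row = u * (K @ v)
        if prev_row is not None and np.max(np.abs(row - prev_row)) < tol:
            converged = True
            break
        prev_row = row
    if not converged:
        warnings.warn(f"unbalanced OT did not converge in {max_iter} iterations")
    gamma = u[:, None] * K * v[None, :]
    return TransportMap(gamma=gamma, epsilon=epsilon, lambda1=lambda1,
                        lambda2=lambda2, source_timepoint=source_timepoint,
                        target_timepoint=target_timepoint,
                        converged=converged, n_iter=it)


def uot_objective(gamma: np.ndarray, C: np.ndarray, a: np.ndarray,
                  b: np.ndarray, epsilon: float, lambda1: float,
                  lambda2: float) -> float:
    """The smooth objective the scaling iterations minimize."""
    g = np.asarray(gamma, dtype=float)
    glog = np.where(g > 0, g * np.log(np.maximum(g, 1e-300)), 0.0)
    ent = -(glog - g).sum()  # H(g) = -sum g (log g - 1)
    r = g.sum(axis=1)
    c = g.sum(axis=0)

    def kl(x, y):
        xlog = np.where(x > 0, x * np.log(np.maximum(x, 1e-300) / y), 0.0)
        return float(xlog.sum() - x.sum() + y.sum())

    return float((C * g).sum() - epsilon * ent + lambda1 * kl(r, a)
                 + lambda2 * kl(c, b))


def learn_growth(embeddings: dict[float, np.ndarray],
                 expected_totals: dict[float, float],
                 epsilon: float = 0.05, lambda1: float = 1.0,
                 lambda2: float = 50.0, n_iter: int = 20,
                 max_iter: int = 5000, tol: float = 1e-8,
                 barcodes: dict[float, list[str]] | None = None
                 ) -> tuple[GrowthModel, list[TransportMap]]:
    """Alternate transport solves and growth updates over all interval pairs.

    Iteration 0 assumes divisions are uniform: every cell at time t gets
    g_i = (N_{t+1}/N_t)^(1/dt). Each subsequent iteration solves all
    consecutive maps with source weights proportional to g_i^dt (total mass
    N_{t+1}/N_t, target uniform with matching mass) and re-reads growth from
    the realized row marginals: g_i^dt = n_t * p_i * (N_{t+1}/N_t) with p
    the normalized row-marginal distribution — a cell transporting more
    mass than average is inferred to divide faster.
    """
    tps = sorted(embeddings)
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")
    for t in tps:
        if expected_totals[t] <= 0:
            raise ValueError("expected totals must be positive")
    growth: dict[float, np.ndarray] = {}
    for t, t1 in zip(tps[:-1], tps[1:]):
        dt = t1 - t
        ratio = expected_totals[t1] / expected_totals[t]
        growth[t] = np.full(embeddings[t].shape[0], ratio ** (1.0 / dt))
    costs = {t: cost_matrix(embeddings[t], embeddings[t1])
             for t, t1 in zip(tps[:-1], tps[1:])}
    maps: list[TransportMap] = []
    for _ in range(n_iter):
        maps = []
        for t, t1 in zip(tps[:-1], tps[1:]):
            dt = t1 - t
            ratio = expected_totals[t1] / expected_totals[t]
            n_t = embeddings[t].shape[0]
            n_t1 = embeddings[t1].shape[0]
            a = growth[t] ** dt
            a = a / a.sum() * ratio
            b = np.full(n_t1, ratio / n_t1)
            tm = solve_unbalanced_ot(costs[t], a, b, epsilon, lambda1, lambda2,
                                     max_iter=max_iter, tol=tol,
                                     source_timepoint=t, target_timepoint=t1)
            if barcodes is not None:
                tm.source_barcodes = barcodes[t]
                tm.target_barcodes = barcodes[t1]
            maps.append(tm)
            rows = tm.gamma.sum(axis=1)
            p = rows / rows.sum()
            growth[t] = (n_t * p * ratio) ** (1.0 / dt)
    if maps and not all(m.converged for m in maps):
        warnings.warn("some transport maps did not converge in final iteration")
    model = GrowthModel(g=growth, expected_totals=dict(expected_totals))
    return model, maps


def compose_maps(maps: list[TransportMap], from_t: float,
                 to_t: float) -> tuple[np.ndarray, np.ndarray]:
    """Chain row-normalized couplings into one Markov matrix from_t -> to_t.

    Returns (matrix, zero_mass_flags); flagged rows had no transported mass
    somewhere along the chain and are excluded downstream rather than
    renormalized.
    """
    chain = sorted((m for m in maps
                    if from_t <= m.source_timepoint and m.target_timepoint <= to_t),
                   key=lambda m: m.source_timepoint)
    if not chain or chain[0].source_timepoint != from_t \
            or chain[-1].target_timepoint != to_t:
        raise ValueError(f"no contiguous chain of maps from {from_t} to {to_t}")
    for m0, m1 in zip(chain[:-1], chain[1:]):
        if m0.target_timepoint != m1.source_timepoint:
            raise ValueError(
                f"gap in chain at {m0.target_timepoint} -> {m1.source_timepoint}"
            )
    out, zero = chain[0].row_stochastic()
    for m in chain[1:]:
        step, step_zero = m.row_stochastic()
        out = out @ step
        rowsums = out.sum(axis=1)
        zero = zero | (rowsums < 1e-12)
    return out, zero


def fate_probabilities(maps: list[TransportMap],
                       fate_sets: dict[str, np.ndarray],
                       from_t: float, reference_t: float,
                       barcodes: list[str] | None = None) -> FateMatrix:
    """P(fate F | cell x at from_t) = sum over y in F of M_xy,
    M the composed Markov matrix from_t -> reference_t."""
    for name, idx in fate_sets.items():
        if np.asarray(idx).size == 0:
            raise ValueError(f"empty fate set {name!r}")
    if from_t == reference_t:
        n = next(m.gamma.shape[1] for m in maps
                 if m.target_timepoint == reference_t)
        M = np.eye(n)
        zero = np.zeros(n, dtype=bool)
    else:
        M, zero = compose_maps(maps, from_t, reference_t)
    fate_names = list(fate_sets)
    probs = np.column_stack([
        M[:, np.asarray(fate_sets[name])].sum(axis=1) for name in fate_names
    ])
    return FateMatrix(probs=probs, fate_names=fate_names,
                      reference_timepoint=reference_t, barcodes=barcodes,
                      zero_mass=zero)
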