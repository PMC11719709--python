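"""Independent reference implementations used only to check the package.

Every oracle here reaches its answer by a different route than the library:
the unbalanced-transport oracle maximizes the smooth dual with BFGS, the
balanced oracle is a plain Sinkhorn loop, the EMD oracles use the dual
linear program and the Hungarian assignment, and the counting oracles are
explicit double loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog, minimize


def uot_dual_oracle(C, a, b, eps, lam1, lam2):
    """Optimal coupling via BFGS on the dual potentials (f, g)."""
    C = np.asarray(C, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = C.shape

    def neg_dual(z):
        f, g = z[:n], z[n:]
        gam = np.exp((f[:, None] + g[None, :] - C) / eps)
        d = (-lam1 * (a * (np.exp(-f / lam1) - 1)).sum()
             - lam2 * (b * (np.exp(-g / lam2) - 1)).sum()
             - eps * gam.sum())
        grad_f = a * np.exp(-f / lam1) - gam.sum(axis=1)
        grad_g = b * np.exp(-g / lam2) - gam.sum(axis=0)
        return -d, -np.concatenate([grad_f, grad_g])

    res = minimize(neg_dual, np.zeros(n + m), jac=True, method="BFGS",
                   options={"maxiter": 20000, "gtol": 1e-13})
    f, g = res.x[:n], res.x[n:]
    return np.exp((f[:, None] + g[None, :] - C) / eps)


def balanced_sinkhorn(C, a, b, eps, n_iter=20000):
    """Textbook balanced Sinkhorn iterations."""
    K = np.exp(-np.asarray(C, float) / eps)
    u = np.ones(len(a))
    v = np.ones(len(b))
    for _ in range(n_iter):
        u = a / (K @ v)
        v = b / (K.T @ u)
    return u[:, None] * K * v[None, :]


def emd_dual_lp(points_x, weights_x, points_y, weights_y):
    """EMD via the dual LP: max <a,f> + <b,g> s.t. f_i + g_j <= D_ij."""
    from scipy.spatial.distance import cdist

    a = np.asarray(weights_x, float)
    a = a / a.sum()
    b = np.asarray(weights_y, float)
    b = b / b.sum()
    D = cdist(points_x, points_y)
    n, m = D.shape
    # variables z = (f, g); maximize a.f + b.g  ->  minimize -(a.f + b.g)
    A_ub = np.zeros((n * m, n + m))
    for i in range(n):
        for j in range(m):
            A_ub[i * m + j, i] = 1.0
            A_ub[i * m + j, n + j] = 1.0
    res = linprog(-np.concatenate([a, b]), A_ub=A_ub, b_ub=D.ravel(),
                  bounds=(None, None), method="highs")
    assert res.success
    return -res.fun


def emd_assignment_oracle(points_x, points_y):
    """EMD of two equal-size uniform clouds via the Hungarian algorithm."""
    from scipy.spatial.distance import cdist

    D = cdist(points_x, points_y)
    r, c = linear_sum_assignment(D)
    return D[r, c].sum() / len(points_x)


def brute_force_coexpression(counts_r, counts_t):
    """Explicit per-cell tally of co-expression classes."""
    n_co = n_low = n_high = 0
    for a, b in zip(counts_r, counts_t):
        if a >= 1 and b >= 1:
            n_co += 1
            if a >= 2 and b >= 2:
                n_high += 1
            else:
                n_low += 1
    return n_co, n_low, n_high


def brute_force_filter(counts, min_genes, max_genes, max_counts):
    """Survivor indices by explicit per-cell recount."""
    keep = []
    arr = np.asarray(counts.todense()) if hasattr(counts, "todense") else counts
    for c in range(arr.shape[1]):
        col = arr[:, c]
        ng = int((col > 0).sum())
        tot = int(col.sum())
        if min_genes < ng < max_genes and tot < max_counts:
            keep.append(c)
    return keep
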